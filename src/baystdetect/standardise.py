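"""Expected counts and area-level covariates from stratified population tables.

Expected counts E_i play the role of the Poisson offset: the events an area
would record per month if national age-sex-specific rates applied to its
registered population.  Rates are pooled over the whole study region
(internal standardisation), so by construction sum(E_i) * T reproduces the
national event total.  E_i is time-constant; all seasonality is carried by
the temporal random effects of the model.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

POP_COLUMNS = ["area", "age_band", "sex", "count"]


class StandardisationError(ValueError):
    pass


def validate_population(population: pd.DataFrame) -> pd.DataFrame:
    """Check a stratified population table (area, age_band, sex, count)."""
    missing = [c for c in POP_COLUMNS if c not in population.columns]
    if missing:
        raise StandardisationError(f"population table missing columns: {missing}")
    pop = population[POP_COLUMNS].copy()
    if pop.duplicated(subset=["area", "age_band", "sex"]).any():
        dup = pop[pop.duplicated(subset=["area", "age_band", "sex"], keep=False)]
        raise StandardisationError(
            f"duplicate (area, age_band, sex) rows:\n{dup.head()}"
        )
    if (pop["count"] < 0).any():
        raise StandardisationError("negative person counts in population table")
    return pop


def pooled_reference_rates(
    stratum_events: pd.DataFrame, population: pd.DataFrame
) -> pd.DataFrame:
    """Stratum-specific event rates pooled over all areas.

    Parameters
    ----------
    stratum_events : DataFrame with columns age_band, sex, events
        Event totals per stratum over the whole study window and region.
    population : stratified population table (area, age_band, sex, count).

    Returns
    -------
    DataFrame with columns age_band, sex, rate where
    rate_g = total events in stratum g / total persons in stratum g.
    """
    pop = validate_population(population)
    persons = (
        pop.groupby(["age_band", "sex"], sort=False)["count"].sum().reset_index()
    )
    merged = persons.merge(stratum_events, on=["age_band", "sex"], how="left")
    merged["events"] = merged["events"].fillna(0.0)
    zero_pop = merged["count"] == 0
    if (zero_pop & (merged["events"] > 0)).any():
        bad = merged.loc[zero_pop & (merged["events"] > 0), ["age_band", "sex"]]
        raise StandardisationError(
            f"strata with events but zero national persons:\n{bad}"
        )
    if zero_pop.any():
        warnings.warn(
            "strata with zero persons and zero events assigned rate 0",
            stacklevel=2,
        )
    rate = np.zeros(len(merged))
    nz = ~zero_pop
    rate[nz] = merged.loc[nz, "events"] / merged.loc[nz, "count"]
    out = merged[["age_band", "sex"]].copy()
    out["rate"] = rate
    return out


def expected_counts(
    population: pd.DataFrame, rates: pd.DataFrame, n_times: int = 1
) -> pd.Series:
    """E_i = sum over strata g of n_ig * rate_g, indexed by area label.

    ``n_times`` divides the result so E_i can be expressed per time point
    when the reference rates cover the whole study window (the model uses a
    time-constant monthly offset; seasonality lives in the temporal random
    effects).  Areas with zero population get E_i = 0 and are flagged with a
    warning; the model layer excludes them before sampling (log E_i
    undefined).
    """
    if n_times < 1:
        raise StandardisationError("n_times must be >= 1")
    pop = validate_population(population)
    merged = pop.merge(rates, on=["age_band", "sex"], how="left", indicator=True)
    unmatched = merged.loc[merged["_merge"] == "left_only", ["age_band", "sex"]]
    if len(unmatched):
        strata = unmatched.drop_duplicates().to_records(index=False).tolist()
        raise StandardisationError(f"no reference rate for strata: {strata}")
    merged["expected"] = merged["count"] * merged["rate"] / n_times
    e = merged.groupby("area", sort=False)["expected"].sum()
    # preserve first-appearance area order of the input table
    e = e.reindex(pop["area"].drop_duplicates())
    zero = e[e == 0].index.tolist()
    if zero:
        log.warning("areas with zero expected count (will be excluded): %s", zero)
    e.name = "expected"
    return e


def covariates(population: pd.DataFrame, active_bands) -> pd.DataFrame:
    """Per-area percent active population and male:female ratio.

    ``active_bands`` is the set of age-band labels counted as working-age
    (15-64 in the motivating application).  Sex labels are matched
    case-insensitively on their first character (m/f).
    """
    pop = validate_population(population)
    active_bands = {str(b) for b in active_bands}
    unknown = active_bands - set(pop["age_band"].astype(str))
    if unknown:
        raise StandardisationError(f"active bands not in population table: {sorted(unknown)}")
    sex_key = pop["sex"].astype(str).str[0].str.lower()
    if not sex_key.isin(["m", "f"]).all():
        bad = sorted(pop.loc[~sex_key.isin(["m", "f"]), "sex"].unique())
        raise StandardisationError(f"unrecognised sex labels: {bad}")
    df = pop.assign(
        _active=pop["age_band"].astype(str).isin(active_bands),
        _sex=sex_key,
    )
    g = df.groupby("area", sort=False)
    total = g["count"].sum()
    active = df[df["_active"]].groupby("area", sort=False)["count"].sum()
    male = df[df["_sex"] == "m"].groupby("area", sort=False)["count"].sum()
    female = df[df["_sex"] == "f"].groupby("area", sort=False)["count"].sum()
    order = pop["area"].drop_duplicates()
    total = total.reindex(order)
    active = active.reindex(order).fillna(0.0)
    male = male.reindex(order).fillna(0.0)
    female = female.reindex(order).fillna(0.0)
    if (female == 0).any():
        bad = female[female == 0].index.tolist()
        raise StandardisationError(f"zero female persons in areas {bad}: m:f ratio undefined")
    if (total == 0).any():
        bad = total[total == 0].index.tolist()
        raise StandardisationError(f"zero total persons in areas {bad}")
    return pd.DataFrame(
        {
            "pct_active": 100.0 * active / total,
            "mf_ratio": male / female,
        },
        index=order,
    )


def quintile_dummies(score: pd.Series) -> pd.DataFrame:
    """Rank areas into 5 equal-count groups and return 4 indicator columns.

    The lowest quintile is the reference (all-zero row).  Ties are broken by
    stable input order; when the area count is not divisible by 5, the
    remainder goes to the lower quintiles first.
    """
    score = pd.Series(score)
    if score.nunique() < 5:
        raise StandardisationError(
            f"need at least 5 distinct scores, got {score.nunique()}"
        )
    n = len(score)
    order = np.argsort(score.to_numpy(), kind="stable")
    base, rem = divmod(n, 5)
    sizes = [base + (1 if q < rem else 0) for q in range(5)]
    quintile = np.empty(n, dtype=int)
    start = 0
    for q, s in enumerate(sizes):
        quintile[order[start : start + s]] = q
        start += s
    cols = {f"imd_q{q + 1}": (quintile == q).astype(int) for q in range(1, 5)}
    return pd.DataFrame(cols, index=score.index)


def read_population_csv(path) -> pd.DataFrame:
    return validate_population(pd.read_csv(path))


def read_rates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("age_band", "sex", "rate") if c not in df.columns]
    if missing:
        raise StandardisationError(f"rates file missing columns: {missing}")
    return df


def write_expected_csv(expected: pd.Series, path) -> None:
    expected.rename_axis("area").reset_index().to_csv(path, index=False)


def write_covariates_csv(cov: pd.DataFrame, path) -> None:
    cov.rename_axis("area").reset_index().to_csv(path, index=False)
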