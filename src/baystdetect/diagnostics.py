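"""Convergence diagnostics and posterior summaries.

Implements the classic split-chain potential scale reduction factor (BGR /
Gelman-Rubin), batch-means Monte Carlo standard errors, and the relative-risk
summaries mapped in small-area studies: exp(h_i) spatial residual risk,
exp(gamma_t) national temporal risk, and fitted area trends under the
posterior mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import SpaceTimePanel
from .sampler import PosteriorSamples


class DiagnosticsError(ValueError):
    pass


def bgr(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic for one scalar.

    ``chains`` is (n_chains, n_draws).  Each chain is split in half, then
    R-hat = sqrt(((n-1)/n W + B/n) / W) over the 2*n_chains half-chains.
    Classic (non-rank-normalised) form.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise DiagnosticsError("need >= 2 chains of draws")
    if chains.shape[1] < 10:
        raise DiagnosticsError("need >= 10 draws per chain")
    half = chains.shape[1] // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = split.shape
    means = split.mean(axis=1)
    W = split.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0  # identical constant chains
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def mc_error(draws: np.ndarray, batch_size: int | None = None) -> float:
    """Batch-means standard error of the posterior mean of one scalar."""
    x = np.asarray(draws, dtype=float).ravel()
    n = len(x)
    if batch_size is None:
        batch_size = max(1, int(np.floor(np.sqrt(n))))
    n_batches = n // batch_size
    if n_batches < 10:
        raise DiagnosticsError(
            f"need >= 10 batches, got {n_batches} (n={n}, batch={batch_size})"
        )
    means = x[: n_batches * batch_size].reshape(n_batches, batch_size).mean(axis=1)
    if np.allclose(means, means[0]):
        return 0.0
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def effective_sample_size(draws: np.ndarray, batch_size: int | None = None) -> float:
    """Batch-means ESS: var(draws) / mcse^2 (equals n for iid draws)."""
    x = np.asarray(draws, dtype=float).ravel()
    se = mc_error(x, batch_size)
    v = x.var(ddof=1)
    if se == 0 or v == 0:
        return float(len(x))
    return float(v / se**2)


def _monitored(samples: PosteriorSamples, n_fields: int = 10, seed: int = 0):
    """Default monitored scalar set: intercept, scales, hyperparameters, the
    whole gamma vector, and a fixed random subset of h_i and u_i."""
    names = []
    d = samples.draws
    for scalar in ("alpha0", "sigma_h", "sigma_v", "sigma_gamma", "a", "b"):
        if scalar in d:
            names.append((scalar, ()))
    if "gamma" in d:
        names += [("gamma", (t,)) for t in range(d["gamma"].shape[2])]
    rng = np.random.Generator(np.random.PCG64(seed))
    n_areas = len(samples.area_labels)
    idx = rng.choice(n_areas, size=min(n_fields, n_areas), replace=False)
    for fieldname in ("h", "u"):
        if fieldname in d:
            names += [(fieldname, (int(i),)) for i in sorted(idx)]
    if "beta" in d and d["beta"].shape[2:] != (0,):
        names += [("beta", (j,)) for j in range(d["beta"].shape[2])]
    return names


def convergence_table(
    samples: PosteriorSamples, monitored=None, batch_size: int | None = None
) -> pd.DataFrame:
    """R-hat, MC error and ESS for each monitored scalar."""
    monitored = monitored or _monitored(samples)
    rows = []
    for name, idx in monitored:
        arr = samples.draws[name][(slice(None), slice(None)) + idx]
        label = name if not idx else f"{name}[{','.join(map(str, idx))}]"
        rhat = bgr(arr) if arr.shape[0] >= 2 else np.nan
        se = mc_error(arr.reshape(-1), batch_size)
        ess = effective_sample_size(arr.reshape(-1), batch_size)
        rows.append((label, rhat, se, ess))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "mc_error", "ess"])


@dataclass
class RiskSummary:
    """Posterior relative-risk summaries (means and 95% equal-tailed CIs)."""

    spatial: pd.DataFrame  # area, mean, lo, hi of exp(h_i)
    temporal: pd.DataFrame  # time, mean, lo, hi of exp(gamma_t)
    trends: pd.DataFrame  # area, time, fitted, lo, hi of mu_it (mixture)
    trends_common: pd.DataFrame
    trends_areaspec: pd.DataFrame


def _summary_frame(draws: np.ndarray, labels, colname: str) -> pd.DataFrame:
    mean = draws.mean(axis=0)
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
    return pd.DataFrame({colname: labels, "mean": mean, "lo": lo, "hi": hi})


def risk_summaries(samples: PosteriorSamples, panel: SpaceTimePanel) -> RiskSummary:
    """Exponentiate and summarise the posterior fields.

    Fitted trends are assembled draw-by-draw under that draw's mixture
    indicator (z_i = 1: common surface; z_i = 0: area-specific trend), so
    the trend bands reflect model-selection uncertainty as well.
    """
    eh = np.exp(samples.stacked("h"))
    eg = np.exp(samples.stacked("gamma"))
    spatial = _summary_frame(eh, list(samples.area_labels), "area")
    temporal = _summary_frame(eg, list(samples.time_labels), "time")

    alpha0 = samples.stacked("alpha0")[:, None, None]
    h = samples.stacked("h")[:, :, None]
    gamma = samples.stacked("gamma")[:, None, :]
    u = samples.stacked("u")[:, :, None]
    K = samples.stacked("K")
    z = samples.stacked("z")[:, :, None].astype(float)
    if panel.X is not None and "beta" in samples.draws and samples.draws["beta"].shape[-1] > 0:
        # covariate term is shared by both components, so it shifts levels
        # but not the mixture choice; include it in the fitted rates
        xb = np.einsum("dp,np->dn", samples.stacked("beta"), panel.X)[:, :, None]
    else:
        xb = 0.0
    LC = alpha0 + h + gamma
    LAS = u + K
    mix = z * LC + (1.0 - z) * LAS
    mu = np.exp(mix + xb)
    n_areas, n_times = len(samples.area_labels), len(samples.time_labels)
    area_col = np.repeat(samples.area_labels, n_times)
    time_col = np.tile(samples.time_labels, n_areas)

    def trend_frame(draws_nt):
        flat = draws_nt.reshape(draws_nt.shape[0], -1)
        mean = flat.mean(axis=0)
        lo, hi = np.quantile(flat, [0.025, 0.975], axis=0)
        return pd.DataFrame(
            {"area": area_col, "time": time_col, "fitted": mean, "lo": lo, "hi": hi}
        )

    return RiskSummary(
        spatial=spatial,
        temporal=temporal,
        trends=trend_frame(mu),
        trends_common=trend_frame(np.exp(LC + xb)),
        trends_areaspec=trend_frame(np.exp(LAS + xb)),
    )


def cross_source_correlation(rr_a: pd.Series, rr_b: pd.Series):
    """Pearson correlation of two per-area risk summaries (e.g. posterior
    mean exp(h_i) from two data sources), plus the low/high agreement
    partition: areas jointly below or jointly above relative risk 1.

    Returns (r, partition DataFrame with columns area, agree_low, agree_high).
    """
    a = pd.Series(rr_a).astype(float)
    b = pd.Series(rr_b).astype(float)
    if set(a.index) != set(b.index):
        raise DiagnosticsError("risk summaries cover different area sets")
    b = b.reindex(a.index)
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        raise DiagnosticsError("zero variance in a risk summary")
    r = float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])
    partition = pd.DataFrame(
        {
            "area": a.index.astype(str),
            "agree_low": ((a < 1) & (b < 1)).to_numpy(),
            "agree_high": ((a > 1) & (b > 1)).to_numpy(),
        }
    )
    return r, partition


def trace_csv(samples: PosteriorSamples, name: str, idx: tuple, path) -> None:
    """Per-scalar trace data (chain, draw, value) for external plotting."""
    arr = samples.draws[name][(slice(None), slice(None)) + idx]
    n_chains, n_draws = arr.shape
    pd.DataFrame(
        {
            "chain": np.repeat(np.arange(n_chains), n_draws),
            "draw": np.tile(np.arange(n_draws), n_chains),
            "value": arr.ravel(),
        }
    ).to_csv(path, index=False)
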