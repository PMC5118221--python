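"""Model / Results interface over the space-time mixture sampler.

Typical use::

    model = BaySTDetect.from_dataframe(panel_df, edges, area_labels)
    res = model.fit(n_chains=3, n_iter=8000, n_burnin=3000, seed=1)
    print(res.summary())
    report = res.detect()            # unusual-area classification
    conv = res.convergence()         # R-hat / MC error / ESS table
    risks = res.risk_summaries()     # exp(h_i), exp(gamma_t), fitted trends
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, replace

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import McmcSettings, PriorConfig
from .detect import DetectionReport, classify, posterior_model_prob
from .diagnostics import RiskSummary, convergence_table, risk_summaries
from .graphs import SpatialGraph, build_spatial_graph
from .panel import SpaceTimePanel
from .sampler import PosteriorSamples, run_mcmc


class BaySTDetect:
    """Spatio-temporal Poisson mixture model for unusual-area detection.

    Parameters
    ----------
    panel : SpaceTimePanel
        Observed and expected counts (and optional centred covariates).
    graph : SpatialGraph
        Area adjacency; must cover exactly the panel's areas in order.
    priors : PriorConfig, optional
        Mixture weight, scale priors and hyperpriors (defaults follow the
        standard specification: Bernoulli(0.95) indicator, half-Normal(0,1)
        scales, N(a, b^2) on the log area-specific variances).
    """

    def __init__(
        self,
        panel: SpaceTimePanel,
        graph: SpatialGraph,
        priors: PriorConfig | None = None,
    ):
        self.panel = panel
        self.graph = graph
        self.priors = priors or PriorConfig()

    @classmethod
    def from_dataframe(
        cls,
        panel_df: pd.DataFrame,
        edges,
        covariates: pd.DataFrame | None = None,
        priors: PriorConfig | None = None,
    ) -> "BaySTDetect":
        """Build from a long table (area, time, count, expected) and an
        edge list of area-label pairs (or a prebuilt SpatialGraph)."""
        panel = SpaceTimePanel.from_long(panel_df, covariates=covariates)
        if isinstance(edges, SpatialGraph):
            graph = edges
        else:
            graph = build_spatial_graph(edges, panel.area_labels)
        return cls(panel, graph, priors)

    def fit(
        self, settings: McmcSettings | None = None, **overrides
    ) -> "BaySTDetectResults":
        """Run the MCMC and wrap the posterior in a results object.

        ``overrides`` are McmcSettings fields (n_chains, n_iter, n_burnin,
        thin, seed, ...) applied on top of ``settings`` or the defaults.
        """
        settings = settings or McmcSettings()
        if overrides:
            settings = replace(settings, **overrides)
        samples = run_mcmc(self.panel, self.graph, self.priors, settings)
        return BaySTDetectResults(self, samples)


class BaySTDetectResults:
    """Posterior samples plus the derived quantities users actually read."""

    def __init__(self, model: BaySTDetect, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    # -- detection ---------------------------------------------------------
    def posterior_model_prob(self) -> pd.Series:
        """P(area follows the Common Model), pooled over chains."""
        return posterior_model_prob(self.samples)

    def detect(self, threshold: float = 0.05) -> DetectionReport:
        conv = self.convergence()
        max_rhat = float(np.nanmax(conv["rhat"])) if len(conv) else np.nan
        ok = bool(max_rhat <= 1.1) if np.isfinite(max_rhat) else True
        return classify(self.posterior_model_prob(), threshold, diagnostics_ok=ok)

    # -- diagnostics / summaries ------------------------------------------
    def convergence(self, monitored=None) -> pd.DataFrame:
        if self.samples.n_chains < 2:
            return pd.DataFrame(columns=["parameter", "rhat", "mc_error", "ess"])
        return convergence_table(self.samples, monitored=monitored)

    def risk_summaries(self) -> RiskSummary:
        return risk_summaries(self.samples, self.model.panel)

    def summary(self, threshold: float = 0.05) -> str:
        """Plain-text overview: run protocol, scale posteriors, temporal
        relative risks, and the flagged areas."""
        s = self.samples
        st = s.settings
        lines = [
            "Space-time mixture model (BaySTDetect)",
            "=" * 54,
            f"areas: {len(s.area_labels)}   time points: {len(s.time_labels)}"
            f"   covariates: {len(s.covariate_names)}",
            f"chains: {st.n_chains}   iterations: {st.n_iter}   "
            f"burn-in: {st.n_burnin}   thin: {st.thin}   "
            f"stored/chain: {st.n_stored}",
            "",
            "posterior scales (mean):",
        ]
        for name in ("sigma_h", "sigma_v", "sigma_gamma", "a", "b"):
            if name in s.draws:
                lines.append(f"  {name:12s} {s.stacked(name).mean():8.3f}")
        rs = self.risk_summaries()
        lines.append("")
        lines.append("national temporal relative risk exp(gamma_t):")
        for _, row in rs.temporal.iterrows():
            lines.append(
                f"  {row['time']:>6} {row['mean']:6.3f} "
                f"[{row['lo']:5.3f}, {row['hi']:5.3f}]"
            )
        rep = self.detect(threshold)
        lines.append("")
        lines.append(
            f"unusual areas (p_common <= {threshold}): "
            + (", ".join(rep.unusual_areas) if rep.n_unusual else "none")
        )
        lowest = rep.table.iloc[0]
        lines.append(
            f"lowest probability: {lowest['area']} (p = {lowest['p_common']:.3f})"
        )
        if not rep.diagnostics_ok:
            lines.append("WARNING: diagnostics failed (max R-hat > 1.1)")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> None:
        save_samples(self.samples, directory)


def save_samples(samples: PosteriorSamples, directory) -> None:
    """Columnar CSV layout: one file per parameter block, chain-major rows
    (chain, draw, flattened component columns), plus a JSON run manifest."""
    import os

    os.makedirs(directory, exist_ok=True)
    for name, arr in samples.draws.items():
        c, d = arr.shape[:2]
        flat = arr.reshape(c * d, -1)
        if flat.shape[1] == 0:  # e.g. beta with no covariates
            continue
        cols = [f"{name}{i}" for i in range(flat.shape[1])] if flat.shape[1] > 1 else [name]
        df = pd.DataFrame(flat, columns=cols)
        df.insert(0, "draw", np.tile(np.arange(d), c))
        df.insert(0, "chain", np.repeat(np.arange(c), d))
        df.to_csv(f"{directory}/{name}.csv", index=False)
    manifest = {
        "package_version": _pkg_version,
        "python": platform.python_version(),
        "settings": asdict(samples.settings),
        "priors": asdict(samples.priors),
        "chain_seeds": samples.chain_seeds,
        "acceptance": samples.acceptance,
        "area_labels": list(samples.area_labels),
        "time_labels": list(samples.time_labels),
        "covariate_names": list(samples.covariate_names),
        "parameters": {
            name: list(arr.shape) for name, arr in samples.draws.items()
        },
    }
    with open(f"{directory}/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_samples(directory) -> PosteriorSamples:
    with open(f"{directory}/manifest.json") as fh:
        manifest = json.load(fh)
    draws = {}
    for name, shape in manifest["parameters"].items():
        if 0 in shape:
            draws[name] = np.empty(shape)
            continue
        df = pd.read_csv(f"{directory}/{name}.csv")
        arr = df.drop(columns=["chain", "draw"]).to_numpy()
        draws[name] = arr.reshape(shape)
    priors = PriorConfig(**manifest["priors"])
    settings = McmcSettings(**manifest["settings"])
    return PosteriorSamples(
        draws=draws,
        settings=settings,
        priors=priors,
        area_labels=tuple(manifest["area_labels"]),
        time_labels=tuple(manifest["time_labels"]),
        covariate_names=tuple(manifest["covariate_names"]),
        acceptance=manifest["acceptance"],
        chain_seeds=manifest["chain_seeds"],
    )
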