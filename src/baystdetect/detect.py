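"""Classification of unusual areas from posterior mixture-indicator draws.

The pooled posterior mean of z_i estimates the probability that area i
follows the common national trend; areas at or below the threshold (0.05 by
default) are flagged as unusual.  A plain per-area threshold is used, not an
FDR-adjusted rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import PosteriorSamples


class DetectionError(ValueError):
    pass


@dataclass
class DetectionReport:
    """Per-area Common-Model probabilities, ranks, and unusual flags."""

    table: pd.DataFrame  # area, p_common, rank, unusual
    threshold: float
    diagnostics_ok: bool = True

    @property
    def unusual_areas(self) -> list:
        return self.table.loc[self.table["unusual"], "area"].tolist()

    @property
    def n_unusual(self) -> int:
        return int(self.table["unusual"].sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def posterior_model_prob(samples: PosteriorSamples) -> pd.Series:
    """p_i = mean of pooled z_i draws across all chains."""
    if "z" not in samples.draws or samples.draws["z"].size == 0:
        raise DetectionError("no z draws in samples")
    z = samples.stacked("z").astype(float)
    p = pd.Series(z.mean(axis=0), index=list(samples.area_labels), name="p_common")
    return p


def classify(
    p: pd.Series,
    threshold: float = 0.05,
    diagnostics_ok: bool = True,
) -> DetectionReport:
    """Flag areas with p_i <= threshold; rank all areas ascending in p.

    Ties in p are broken by area label (stable), so ranks are always a
    permutation.
    """
    if not 0.0 < threshold < 1.0:
        raise DetectionError(f"threshold must be in (0,1), got {threshold}")
    p = pd.Series(p)
    if not np.isfinite(p.to_numpy(dtype=float)).all():
        raise DetectionError("non-finite probabilities")
    if ((p < 0) | (p > 1)).any():
        raise DetectionError("probabilities outside [0,1]")
    df = pd.DataFrame({"area": p.index.astype(str), "p_common": p.to_numpy()})
    df = df.sort_values(["p_common", "area"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["unusual"] = df["p_common"] <= threshold
    return DetectionReport(table=df, threshold=threshold, diagnostics_ok=diagnostics_ok)


def detect(
    samples: PosteriorSamples,
    threshold: float = 0.05,
    max_rhat: float | None = None,
) -> DetectionReport:
    """posterior_model_prob + classify, with an advisory convergence stamp.

    ``max_rhat`` is the largest split-chain R-hat over monitored scalars, if
    the caller computed one; above 1.1 the report is still produced but
    stamped diagnostics_ok=False.
    """
    p = posterior_model_prob(samples)
    ok = True if max_rhat is None else bool(max_rhat <= 1.1)
    return classify(p, threshold=threshold, diagnostics_ok=ok)
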