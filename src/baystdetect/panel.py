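"""The area x time count panel the model is fitted to."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class PanelError(ValueError):
    pass


@dataclass
class SpaceTimePanel:
    """Observed counts y (N x T), per-area expected counts E, optional
    covariates X (N x p, stored column-centred with the centring constants).

    Every cell of y must be present and nonnegative; E_i must be strictly
    positive (log E_i is the Poisson offset).  Use :func:`from_long` to build
    from a long-format table and drop zero-E areas with a warning.
    """

    y: np.ndarray
    E: np.ndarray
    area_labels: tuple[str, ...]
    time_labels: tuple[str, ...]
    X: np.ndarray | None = None
    covariate_names: tuple[str, ...] = ()
    x_means: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.y = np.asarray(self.y)
        self.E = np.asarray(self.E, dtype=float)
        if self.y.ndim != 2:
            raise PanelError("y must be an N x T matrix")
        n, t = self.y.shape
        if len(self.area_labels) != n or len(self.time_labels) != t:
            raise PanelError("label lengths do not match y shape")
        if np.any(pd.isna(self.y)):
            raise PanelError("missing cells in y: complete panels required")
        if not np.issubdtype(self.y.dtype, np.integer):
            as_int = self.y.astype(int)
            if not np.array_equal(as_int, self.y):
                raise PanelError("y contains non-integer counts")
            self.y = as_int
        if (self.y < 0).any():
            raise PanelError("negative counts in y")
        if self.E.shape != (n,):
            raise PanelError("E must be length-N")
        if (self.E <= 0).any() or not np.isfinite(self.E).all():
            raise PanelError("E_i must be finite and > 0 (zero-E areas must be dropped)")
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.shape[0] != n:
                raise PanelError("X row count does not match number of areas")
            if self.x_means is None:
                self.x_means = self.X.mean(axis=0)
                self.X = self.X - self.x_means
            if not self.covariate_names:
                self.covariate_names = tuple(
                    f"x{k}" for k in range(self.X.shape[1])
                )

    @property
    def n_areas(self) -> int:
        return self.y.shape[0]

    @property
    def n_times(self) -> int:
        return self.y.shape[1]

    @property
    def n_covariates(self) -> int:
        return 0 if self.X is None else self.X.shape[1]

    @classmethod
    def from_long(
        cls,
        panel: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        area_col: str = "area",
        time_col: str = "time",
        count_col: str = "count",
        expected_col: str = "expected",
    ) -> "SpaceTimePanel":
        """Build from a long table with one row per (area, time).

        ``expected`` may vary only by area; areas with E <= 0 are dropped
        with a warning rather than failing the whole panel.
        """
        for c in (area_col, time_col, count_col, expected_col):
            if c not in panel.columns:
                raise PanelError(f"panel table missing column {c!r}")
        wide = panel.pivot_table(
            index=area_col, columns=time_col, values=count_col, aggfunc="sum",
            sort=False,
        )
        wide = wide[sorted(wide.columns)]
        if wide.isna().any().any():
            missing = wide.isna().sum().sum()
            raise PanelError(f"{missing} missing (area, time) cells in panel")
        e = panel.groupby(area_col, sort=False)[expected_col].first()
        e = e.reindex(wide.index)
        per_area_var = panel.groupby(area_col, sort=False)[expected_col].nunique()
        if (per_area_var > 1).any():
            raise PanelError("expected counts must be constant within area")
        keep = e > 0
        if (~keep).any():
            log.warning(
                "dropping %d areas with nonpositive expected counts: %s",
                (~keep).sum(), list(e.index[~keep]),
            )
        wide, e = wide[keep], e[keep]
        labels = tuple(str(a) for a in wide.index)
        X = names = None
        if covariates is not None:
            cov = covariates.reindex(wide.index)
            if cov.isna().any().any():
                raise PanelError("covariates missing for some panel areas")
            X = cov.to_numpy(dtype=float)
            names = tuple(cov.columns)
        return cls(
            y=wide.to_numpy(),
            E=e.to_numpy(dtype=float),
            area_labels=labels,
            time_labels=tuple(str(t) for t in wide.columns),
            X=X,
            covariate_names=names or (),
        )

    def to_long(self) -> pd.DataFrame:
        rows = {
            "area": np.repeat(self.area_labels, self.n_times),
            "time": np.tile(self.time_labels, self.n_areas),
            "count": self.y.ravel(),
            "expected": np.repeat(self.E, self.n_times),
        }
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, covariates_path=None) -> "SpaceTimePanel":
        cov = None
        if covariates_path is not None:
            cov = pd.read_csv(covariates_path).set_index("area")
            cov.index = cov.index.astype(str)
        df = pd.read_csv(path)
        df["area"] = df["area"].astype(str)
        return cls.from_long(df, covariates=cov)
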