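"""Synthetic monthly count panels with known ground truth.

Emulates the structure of small-area health surveillance data: N areas on an
adjacency graph observed over T months, Poisson counts around a shared smooth
spatial surface (BYM convolution) and a shared seasonal trend peaking
mid-series (a winter analogue), with a small injected fraction of areas whose
trend deviates from the national one.  The generator is the source of every
test panel: detection sensitivity/specificity, parameter recovery and null
behaviour are all measured against its ground truth.

Magnitudes are stylised, not calibrated to any real prescription or
admission series: expected counts of a few hundred events per area-month and
log-scale deviations around 0.7 give the contrast regime in which a
seasonal national trend is clearly estimable and strong deviations are
detectable over an 8-month window.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .graphs import (
    IcarStructure,
    SpatialGraph,
    build_spatial_graph,
    build_temporal_graph,
    icar_structure,
)
from .panel import SpaceTimePanel

_SHAPES = ("flat", "shifted_peak", "ramp", "spike")
_LOG_MU_CLIP = 20.0


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator.

    Defaults emulate the motivating setting: 211 areas on an irregular
    planar graph, 8 monthly time points, a seasonal trend peaking at t=5
    (December analogue for an August-to-March window), and expected counts
    of 100-500 events per area-month.
    """

    n_areas: int = 211
    grid: tuple | None = None  # (rows, cols) rook grid instead of planar graph
    n_times: int = 8
    alpha0: float = 0.0
    sigma_v: float = 0.3
    sigma_h: float = 0.15
    sigma_gamma: float = 0.05
    seasonal_amplitude: float = 0.4
    peak_time: int = 4  # 0-based: 5th month
    frac_unusual: float = 0.0
    unusual_areas: tuple = ()
    deviation_shape: str = "flat"
    deviation_magnitude: float = 0.7
    spike_time: int | None = None
    shift_offset: int = 2
    expected_range: tuple = (100.0, 500.0)
    covariate_effects: dict = field(default_factory=dict)
    # population generator (feeds the standardisation module)
    persons_per_area: float = 50_000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_times < 2:
            raise SimulationError("n_times must be >= 2")
        if not 0.0 <= self.frac_unusual <= 0.2:
            raise SimulationError("frac_unusual must be in [0, 0.2]")
        for s in ("sigma_v", "sigma_h", "sigma_gamma"):
            if getattr(self, s) <= 0:
                raise SimulationError(f"{s} must be > 0")
        if self.deviation_shape not in _SHAPES:
            raise SimulationError(
                f"deviation_shape must be one of {_SHAPES}, got {self.deviation_shape!r}"
            )
        lo, hi = self.expected_range
        if not 0 < lo <= hi:
            raise SimulationError("expected_range must satisfy 0 < lo <= hi")


@dataclass
class GroundTruth:
    """The latent fields and labels a synthetic panel was generated from."""

    alpha0: float
    h: np.ndarray
    v: np.ndarray
    gamma: np.ndarray
    K_unusual: dict  # area index -> length-T deviating trend
    z: np.ndarray  # 1 = follows the common trend
    beta: np.ndarray
    area_labels: tuple

    @property
    def unusual_indices(self) -> np.ndarray:
        return np.where(self.z == 0)[0]

    def to_json(self, path) -> None:
        payload = {
            "alpha0": self.alpha0,
            "h": self.h.tolist(),
            "v": self.v.tolist(),
            "gamma": self.gamma.tolist(),
            "K_unusual": {str(k): v.tolist() for k, v in self.K_unusual.items()},
            "z": self.z.tolist(),
            "beta": self.beta.tolist(),
            "area_labels": list(self.area_labels),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def load_simulation_config(path) -> SimulationConfig:
    """Read a SimulationConfig from YAML (see default_simulation.yaml)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("grid", "unusual_areas", "expected_range"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def dump_simulation_config(config: SimulationConfig, path) -> None:
    import yaml
    from dataclasses import asdict

    raw = asdict(config)
    for key in ("grid", "unusual_areas", "expected_range"):
        if raw[key] is not None:
            raw[key] = list(raw[key])
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


_STREAMS = {"graph": 11, "surface": 23, "inject": 37, "panel": 51, "population": 67}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible substream so each stage can be replayed alone."""
    if name not in _STREAMS:
        raise SimulationError(f"unknown stream {name!r}")
    ss = np.random.SeedSequence([int(seed) % (2**31), _STREAMS[name]])
    return np.random.Generator(np.random.PCG64(ss))


def grid_graph(rows: int, cols: int) -> SpatialGraph:
    """Rook-adjacency grid; convenient regular geography for tests."""
    labels = [f"g{r}_{c}" for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((f"g{r}_{c}", f"g{r}_{c + 1}"))
            if r + 1 < rows:
                edges.append((f"g{r}_{c}", f"g{r + 1}_{c}"))
    return build_spatial_graph(edges, labels)


def random_planar_graph(n_areas: int, rng: np.random.Generator) -> SpatialGraph:
    """Delaunay triangulation of random points: an irregular planar adjacency
    resembling an administrative geography."""
    if n_areas < 4:
        raise SimulationError("need at least 4 areas for a triangulation")
    pts = rng.random((n_areas, 2))
    tri = Delaunay(pts)
    labels = [f"a{i:03d}" for i in range(n_areas)]
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((labels[a], labels[b]))
    return build_spatial_graph(sorted(edges), labels)


def sample_icar(structure: IcarStructure, sigma: float, rng) -> np.ndarray:
    """Draw from the ICAR distribution constrained to sum to zero on each
    connected component.

    Uses the eigenbasis of R: independent N(0, sigma^2/lambda_j) coefficients
    on the non-null eigenvectors; null directions (per-component constants)
    are excluded, which enforces the constraints exactly.
    """
    if sigma <= 0:
        raise SimulationError(f"sigma must be > 0, got {sigma}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.Generator(np.random.PCG64(rng))
    R = structure.R.toarray()
    lam, vecs = np.linalg.eigh(R)
    keep = lam > 1e-9
    coeff = rng.standard_normal(int(keep.sum())) * sigma / np.sqrt(lam[keep])
    return vecs[:, keep] @ coeff


def seasonal_profile(n_times: int, amplitude: float, peak_time: int) -> np.ndarray:
    """Deterministic centred bump peaking at ``peak_time`` — the shared
    seasonal trend skeleton (winter peak analogue)."""
    t = np.arange(n_times, dtype=float)
    width = max(n_times / 4.0, 1.0)
    bump = np.exp(-0.5 * ((t - peak_time) / width) ** 2)
    bump = bump - bump.mean()
    if bump.std() < 1e-12:
        return np.zeros(n_times)
    return amplitude * bump / (bump.max() - bump.min())


def make_common_surface(
    config: SimulationConfig,
    spatial_structure: IcarStructure,
    temporal_structure: IcarStructure,
    rng,
) -> GroundTruth:
    """Draw the shared surface: v ~ ICAR(sigma_v), h_i ~ N(v_i, sigma_h^2),
    gamma = seasonal bump + ICAR(sigma_gamma) noise, centred."""
    n = spatial_structure.n
    t = temporal_structure.n
    v = sample_icar(spatial_structure, config.sigma_v, rng)
    h = v + config.sigma_h * rng.standard_normal(n)
    gamma = seasonal_profile(t, config.seasonal_amplitude, config.peak_time)
    gamma = gamma + sample_icar(temporal_structure, config.sigma_gamma, rng)
    gamma = gamma - gamma.mean()
    beta = np.array([val for _, val in sorted(config.covariate_effects.items())])
    return GroundTruth(
        alpha0=config.alpha0,
        h=h,
        v=v,
        gamma=gamma,
        K_unusual={},
        z=np.ones(n, dtype=np.int8),
        beta=beta,
        area_labels=tuple(f"a{i:03d}" for i in range(n)),
    )


def deviation_trend(
    gamma: np.ndarray,
    shape: str,
    magnitude: float,
    spike_time: int | None = None,
    shift_offset: int = 2,
) -> np.ndarray:
    """The centred area-specific trend that replaces the common one."""
    T = len(gamma)
    if shape == "flat":
        k = np.zeros(T)
    elif shape == "shifted_peak":
        k = np.roll(gamma, shift_offset)
    elif shape == "ramp":
        k = magnitude * (np.arange(T) / (T - 1) - 0.5)
    elif shape == "spike":
        st = spike_time if spike_time is not None else int(np.argmin(gamma))
        k = gamma.copy()
        k[st] += magnitude
    else:
        raise SimulationError(f"unknown deviation shape {shape!r}")
    return k - k.mean()


def inject_unusual(
    truth: GroundTruth,
    area_ids,
    shape: str = "flat",
    magnitude: float = 0.7,
    spike_time: int | None = None,
    shift_offset: int = 2,
) -> GroundTruth:
    """Replace the common trend with a deviating one for the chosen areas
    (z flipped to 0).  Returns a new GroundTruth; the input is untouched."""
    if shape not in _SHAPES:
        raise SimulationError(f"unknown deviation shape {shape!r}")
    if magnitude == 0 and shape != "flat":
        warnings.warn("deviation magnitude 0: injected areas are undetectable",
                      stacklevel=2)
    n = len(truth.z)
    ids = [int(i) for i in area_ids]
    if len(set(ids)) != len(ids):
        raise SimulationError("duplicate unusual area ids")
    if any(i < 0 or i >= n for i in ids):
        raise SimulationError(f"area ids out of range [0, {n})")
    z = truth.z.copy()
    K = dict(truth.K_unusual)
    for i in ids:
        K[i] = deviation_trend(truth.gamma, shape, magnitude, spike_time, shift_offset)
        z[i] = 0
    return GroundTruth(
        alpha0=truth.alpha0, h=truth.h, v=truth.v, gamma=truth.gamma,
        K_unusual=K, z=z, beta=truth.beta, area_labels=truth.area_labels,
    )


def true_log_mu(truth: GroundTruth, X: np.ndarray | None = None) -> np.ndarray:
    """N x T matrix of true log relative risks under the generating mixture.

    Usual areas follow alpha0 + h_i + gamma_t; unusual areas keep their level
    alpha0 + h_i but follow their own centred trend k_i instead of gamma."""
    n = len(truth.z)
    T = len(truth.gamma)
    L = truth.alpha0 + truth.h[:, None] + truth.gamma[None, :]
    for i, k in truth.K_unusual.items():
        L[i] = truth.alpha0 + truth.h[i] + k
    if X is not None and truth.beta.size:
        L = L + (X @ truth.beta)[:, None]
    return L


def generate_panel(
    truth: GroundTruth,
    expected: np.ndarray,
    rng,
    X: np.ndarray | None = None,
    covariate_names: tuple = (),
    time_labels: tuple | None = None,
) -> SpaceTimePanel:
    """Poisson counts y_it ~ Poisson(E_i * mu_it) around the true surface."""
    E = np.asarray(expected, dtype=float)
    n, T = len(truth.z), len(truth.gamma)
    if E.shape != (n,):
        raise SimulationError("expected counts length does not match truth")
    if (E <= 0).any():
        raise SimulationError("expected counts must be positive (drop zero-E areas upstream)")
    L = true_log_mu(truth, X)
    if np.any(np.abs(L) > _LOG_MU_CLIP):
        warnings.warn("clipping |log mu| > 20 in panel generation", stacklevel=2)
        L = np.clip(L, -_LOG_MU_CLIP, _LOG_MU_CLIP)
    y = rng.poisson(E[:, None] * np.exp(L))
    return SpaceTimePanel(
        y=y,
        E=E,
        area_labels=truth.area_labels,
        time_labels=tuple(time_labels or (f"t{t + 1}" for t in range(T))),
        X=X,
        covariate_names=covariate_names,
    )


AGE_BANDS = tuple(
    [f"{lo:02d}-{lo + 4:02d}" for lo in range(0, 85, 5)] + ["85+"]
)
ACTIVE_BANDS = tuple(b for b in AGE_BANDS if b[:2].isdigit() and 15 <= int(b[:2]) <= 60)


def synth_population(config: SimulationConfig, rng) -> pd.DataFrame:
    """Per-area age x sex person counts (5-year bands to 85+).

    Each area gets a slightly different age skew and sex ratio so the
    derived covariates (percent active, m:f ratio) vary between areas."""
    n = config.n_areas if config.grid is None else config.grid[0] * config.grid[1]
    labels = [f"a{i:03d}" for i in range(n)]
    n_bands = len(AGE_BANDS)
    mid = np.arange(n_bands)
    rows = []
    for i, lab in enumerate(labels):
        total = config.persons_per_area * rng.lognormal(0.0, 0.2)
        skew = rng.normal(0.0, 0.15)  # positive -> older area
        w = np.exp(-0.5 * ((mid - (n_bands / 2 + 4 * skew)) / (n_bands / 2)) ** 2)
        w /= w.sum()
        sex_frac_m = np.clip(0.5 + rng.normal(0.0, 0.02), 0.4, 0.6)
        for bi, band in enumerate(AGE_BANDS):
            persons = total * w[bi]
            rows.append((lab, band, "M", int(round(persons * sex_frac_m))))
            rows.append((lab, band, "F", int(round(persons * (1 - sex_frac_m)))))
    return pd.DataFrame(rows, columns=["area", "age_band", "sex", "count"])


def simulate_dataset(config: SimulationConfig):
    """Full pipeline: graph, surface, injections, expected counts, panel.

    Returns (panel, truth, graph).  Each stage uses its own named RNG
    substream derived from ``config.seed``.
    """
    if config.grid is not None:
        graph = grid_graph(*config.grid)
    else:
        graph = random_planar_graph(config.n_areas, substream(config.seed, "graph"))
    spatial = icar_structure(graph)
    temporal = icar_structure(build_temporal_graph(config.n_times))
    truth = make_common_surface(
        config, spatial, temporal, substream(config.seed, "surface")
    )
    truth = GroundTruth(
        alpha0=truth.alpha0, h=truth.h, v=truth.v, gamma=truth.gamma,
        K_unusual={}, z=truth.z, beta=truth.beta,
        area_labels=graph.labels,
    )
    n = graph.n_areas
    rng_inj = substream(config.seed, "inject")
    if config.unusual_areas:
        ids = [graph.label_index()[str(a)] if not isinstance(a, (int, np.integer)) else int(a)
               for a in config.unusual_areas]
    elif config.frac_unusual > 0:
        n_unusual = int(round(config.frac_unusual * n))
        ids = rng_inj.choice(n, size=n_unusual, replace=False).tolist()
    else:
        ids = []
    if ids:
        truth = inject_unusual(
            truth, ids,
            shape=config.deviation_shape,
            magnitude=config.deviation_magnitude,
            spike_time=config.spike_time,
            shift_offset=config.shift_offset,
        )
    rng_panel = substream(config.seed, "panel")
    lo, hi = config.expected_range
    E = rng_panel.uniform(lo, hi, size=n)
    panel = generate_panel(truth, E, rng_panel)
    return panel, truth, graph
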