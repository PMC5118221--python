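"""Prior and MCMC run configuration, with YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PriorConfig:
    """Prior hierarchy of the two-component space-time mixture.

    pi is the prior probability that an area follows the Common Model
    (shared spatial surface + one national trend); 1 - pi that it follows
    its own Area-Specific trend.  The structured-field scales sigma_h,
    sigma_v, sigma_gamma get half-Normal(0, halfnormal_scale^2) priors; the
    per-area temporal variances are pooled through
    log(sigma_ik^2) ~ N(a, b^2) with a ~ N(0, a_prior_var) and b half-Normal
    (an extra hierarchical level needed for identifiability of the
    area-specific fields).
    """

    pi: float = 0.95
    halfnormal_scale: float = 1.0
    u_prior_var: float = 1000.0
    a_prior_var: float = 1000.0
    b_halfnormal_scale: float = 2.5
    beta_prior_var: float = 1000.0
    # cut structure: both components always see the full data and z is a
    # Gibbs draw from the two predictive likelihoods.  strict_mixture=True
    # instead gives each area's likelihood only to its active component.
    strict_mixture: bool = False
    covariates_in_areaspec: bool = True
    likelihood_off: bool = False
    fixed_scales: dict = field(default_factory=dict)

    def __post_init__(self):
        # the endpoints are allowed as degenerate single-component fits
        if not 0.0 <= self.pi <= 1.0:
            raise ConfigError(f"pi must be in [0,1], got {self.pi}")
        for name in ("halfnormal_scale", "u_prior_var", "a_prior_var",
                     "b_halfnormal_scale", "beta_prior_var"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        allowed = {"sigma_h", "sigma_v", "sigma_gamma", "sigma_ik", "a", "b"}
        bad = set(self.fixed_scales) - allowed
        if bad:
            raise ConfigError(f"unknown fixed_scales entries: {sorted(bad)}")


@dataclass
class McmcSettings:
    """Sampler protocol.  Defaults echo the published run: 3 chains of
    80,000 iterations, 20,000 burn-in, keep every 5th draw."""

    n_chains: int = 3
    n_iter: int = 80_000
    n_burnin: int = 20_000
    thin: int = 5
    seed: int = 0
    target_accept: float = 0.44
    adapt: bool = True
    progress_every: int = 0  # iterations between log messages; 0 = silent

    def __post_init__(self):
        if self.n_burnin >= self.n_iter:
            raise ConfigError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if self.n_chains < 1:
            raise ConfigError("need at least one chain")
        if not 0.0 < self.target_accept < 1.0:
            raise ConfigError("target_accept must be in (0,1)")

    @property
    def n_stored(self) -> int:
        """Stored draws per chain after burn-in and thinning."""
        return (self.n_iter - self.n_burnin) // self.thin


def load_config(path) -> tuple[PriorConfig, McmcSettings]:
    """Read a YAML file with optional [priors] and [mcmc] blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return (
        PriorConfig(**(raw.get("priors") or {})),
        McmcSettings(**(raw.get("mcmc") or {})),
    )


def dump_config(priors: PriorConfig, settings: McmcSettings, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"priors": asdict(priors), "mcmc": asdict(settings)}, fh)
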