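"""Metropolis-within-Gibbs sampler for the space-time mixture model.

Observation model: Y_it ~ Poisson(E_i * mu_it) with
log mu_it = z_i * log mu^C_it + (1 - z_i) * log mu^AS_it, where the Common
Model log mu^C_it = alpha0 + h_i + gamma_t (+ x_i'beta) shares one temporal
trend across all areas, and the Area-Specific Model
log mu^AS_it = u_i + k_it (+ x_i'beta) frees each area's trend.

Sampling scheme (one sweep):
  * alpha0, h, gamma, u, K, beta: adaptive single-site random-walk MH,
    vectorised across conditionally independent sites; gamma and the K
    columns are updated in even/odd time blocks because the random-walk
    prior only couples adjacent time points.
  * v (spatial ICAR layer under h): exact joint Gibbs draw from its Gaussian
    full conditional, diagonal in the eigenbasis of the structure matrix R;
    the per-component sum-to-zero constraints are the null directions of R,
    so the constrained draw zeroes those coefficients (isolated areas end up
    pinned at 0).
  * z: Gibbs from the two per-area predictive likelihoods (Bernoulli).
  * scales: MH on the log scale against half-Normal priors; the log-variance
    hyper-mean a is a conjugate Normal draw.

Identifiability: after each sweep gamma is re-centred with the mean absorbed
into alpha0, and every K row is re-centred with the mean absorbed into u_i.
Step sizes adapt toward the target acceptance rate during burn-in only
(Robbins-Monro), then freeze so the post-burn-in kernel satisfies detailed
balance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, expit

from .config import McmcSettings, PriorConfig
from .graphs import IcarStructure, SpatialGraph, build_temporal_graph, icar_structure
from .panel import SpaceTimePanel

log = logging.getLogger(__name__)

_EXP_CLIP = 50.0  # caps exp() arguments in rate computations; beyond this the
# Poisson term is astronomically unlikely anyway and inf would poison the MH ratio


class McmcError(RuntimeError):
    pass


@dataclass
class ModelState:
    """One point in the sampler's state space."""

    alpha0: float
    h: np.ndarray  # (N,) BYM convolution effect, h_i ~ N(v_i, sigma_h^2)
    v: np.ndarray  # (N,) spatially structured layer, ICAR, sum-zero/component
    gamma: np.ndarray  # (T,) shared trend, RW(1), sum-zero
    u: np.ndarray  # (N,) area-specific intercepts
    K: np.ndarray  # (N,T) area-specific trends, RW(1) rows, row-sum-zero
    z: np.ndarray  # (N,) mixture indicators, 1 = Common Model
    sigma_h: float
    sigma_v: float
    sigma_gamma: float
    log_var_ik: np.ndarray  # (N,) log sigma_ik^2
    a: float
    b: float
    beta: np.ndarray  # (p,) covariate coefficients

    def copy(self) -> "ModelState":
        return ModelState(
            alpha0=self.alpha0,
            h=self.h.copy(), v=self.v.copy(), gamma=self.gamma.copy(),
            u=self.u.copy(), K=self.K.copy(), z=self.z.copy(),
            sigma_h=self.sigma_h, sigma_v=self.sigma_v,
            sigma_gamma=self.sigma_gamma,
            log_var_ik=self.log_var_ik.copy(), a=self.a, b=self.b,
            beta=self.beta.copy(),
        )


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws, chain-major: draws[name][c, d, ...]."""

    draws: dict
    settings: McmcSettings
    priors: PriorConfig
    area_labels: tuple
    time_labels: tuple
    covariate_names: tuple
    acceptance: dict
    chain_seeds: list

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_stored(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Pool chains: (n_chains * n_stored, ...)."""
        arr = self.draws[name]
        return arr.reshape((-1,) + arr.shape[2:])


# ---------------------------------------------------------------------------
# spec'd elementary operations

def _xb(state: ModelState, panel: SpaceTimePanel) -> np.ndarray:
    if panel.X is None or state.beta.size == 0:
        return np.zeros(panel.n_areas)
    return panel.X @ state.beta


def log_rate_common(state: ModelState, panel: SpaceTimePanel, i: int, t: int) -> float:
    """alpha0 + h_i + gamma_t + x_i'beta."""
    return float(state.alpha0 + state.h[i] + state.gamma[t] + _xb(state, panel)[i])


def log_rate_areaspec(
    state: ModelState, panel: SpaceTimePanel, i: int, t: int, *,
    covariates_in_areaspec: bool = True,
) -> float:
    """u_i + k_it (+ x_i'beta when covariates are shared across components)."""
    out = float(state.u[i] + state.K[i, t])
    if covariates_in_areaspec:
        out += float(_xb(state, panel)[i])
    return out


def area_log_likelihood(panel: SpaceTimePanel, log_rates: np.ndarray, i: int) -> float:
    """Poisson log-likelihood of area i's row given its T log relative risks:
    sum_t [ y_it (log E_i + l_it) - E_i e^{l_it} - log y_it! ].

    Overflowing rates yield -inf (with a warning), never NaN.
    """
    ell = np.asarray(log_rates, dtype=float)
    y = panel.y[i]
    E = panel.E[i]
    if not np.isfinite(ell).all() or np.any(ell > _EXP_CLIP):
        log.warning("overflowing log rate for area %s", panel.area_labels[i])
        return -np.inf
    lam = E * np.exp(ell)
    ll = np.sum(y * (np.log(E) + ell) - lam - gammaln(y + 1.0))
    return float(ll) if np.isfinite(ll) else -np.inf


def _loglik_rows(y, E, L):
    """Row sums of y*L - E*exp(L) (per-area log-likelihood kernels)."""
    lam = E[:, None] * np.exp(np.clip(L, -_EXP_CLIP, _EXP_CLIP))
    return np.sum(y * L - lam, axis=1)


def gibbs_update_z(
    state: ModelState, panel: SpaceTimePanel, priors: PriorConfig, rng
) -> np.ndarray:
    """Draw z_i ~ Bernoulli(p_i), p_i = pi L^C_i / (pi L^C_i + (1-pi) L^AS_i),
    with the two per-area likelihoods computed in log space."""
    p = posterior_z_probabilities(state, panel, priors)
    return (rng.random(panel.n_areas) < p).astype(np.int8)


def posterior_z_probabilities(
    state: ModelState, panel: SpaceTimePanel, priors: PriorConfig
) -> np.ndarray:
    """Conditional P(z_i = 1 | everything else) for all areas."""
    if priors.likelihood_off or priors.pi in (0.0, 1.0):
        return np.full(panel.n_areas, priors.pi)
    xb = _xb(state, panel)
    LC = state.alpha0 + state.h[:, None] + state.gamma[None, :] + xb[:, None]
    LAS = state.u[:, None] + state.K
    if priors.covariates_in_areaspec:
        LAS = LAS + xb[:, None]
    llC = _loglik_rows(panel.y, panel.E, LC)
    llAS = _loglik_rows(panel.y, panel.E, LAS)
    if np.any(np.isneginf(llC) & np.isneginf(llAS)):
        raise McmcError("both component likelihoods are zero for some area")
    logit = math.log(priors.pi / (1.0 - priors.pi)) + (llC - llAS)
    return expit(logit)


# ---------------------------------------------------------------------------
# sampler internals

@dataclass
class _StepSizes:
    alpha0: float = 0.1
    h: np.ndarray = None
    gamma: np.ndarray = None
    u: np.ndarray = None
    K: np.ndarray = None
    beta: np.ndarray = None
    lsig_h: float = 0.3
    lsig_v: float = 0.3
    lsig_g: float = 0.3
    lv: np.ndarray = None
    lb: float = 0.3

    @classmethod
    def init(cls, n, t, p):
        return cls(
            h=np.full(n, 0.1), gamma=np.full(t, 0.1), u=np.full(n, 0.1),
            K=np.full((n, t), 0.2), beta=np.full(max(p, 1), 0.05),
            lv=np.full(n, 0.5),
        )


class _AcceptLog:
    def __init__(self):
        self.acc = {}
        self.tot = {}

    def add(self, name, accepted, count):
        self.acc[name] = self.acc.get(name, 0.0) + float(accepted)
        self.tot[name] = self.tot.get(name, 0) + int(count)

    def rates(self):
        return {k: self.acc[k] / max(self.tot[k], 1) for k in self.acc}


def _adapt(logstep_exp, acc_frac, target, rate):
    """Robbins-Monro move of log step size toward the target acceptance.
    Bounded: free drift (e.g. a flat-prior scalar with the likelihood
    disabled) accepts everything and would otherwise grow without limit."""
    return np.clip(logstep_exp * np.exp(rate * (acc_frac - target)), 1e-4, 10.0)


class _ChainRunner:
    """One MCMC chain.  Holds precomputed panel summaries and the spatial /
    temporal ICAR structures shared by every update."""

    def __init__(
        self,
        panel: SpaceTimePanel,
        spatial: IcarStructure,
        temporal: IcarStructure,
        priors: PriorConfig,
        settings: McmcSettings,
        rng: np.random.Generator,
    ):
        self.panel = panel
        self.spatial = spatial
        self.temporal = temporal
        self.priors = priors
        self.settings = settings
        self.rng = rng
        self.N, self.T = panel.y.shape
        self.p = panel.n_covariates
        self.sy = panel.y.sum(axis=1).astype(float)  # (N,)
        self.cy = panel.y.sum(axis=0).astype(float)  # (T,)
        self.R_spatial = spatial.R.toarray()
        # eigenbasis of R: the v full conditional is diagonal there, and the
        # per-component sum-to-zero constraints are exactly the null
        # directions, so the constrained Gibbs draw zeroes those coefficients
        lamR, VR = np.linalg.eigh(self.R_spatial)
        self._lamR = np.where(lamR > 1e-9, lamR, 0.0)
        self._VR = VR
        self._null = lamR <= 1e-9
        lamT, VT = np.linalg.eigh(temporal.R.toarray())
        keep = lamT > 1e-9
        self._lamT = lamT[keep]
        self._VT = VT[:, keep]
        self.steps = _StepSizes.init(self.N, self.T, self.p)
        self.accept = _AcceptLog()

    # -- likelihood weights per component --------------------------------
    def _weights(self, state):
        """Per-area likelihood weight for (common, area-specific) fields."""
        if self.priors.likelihood_off:
            zero = np.zeros(self.N)
            return zero, zero
        if self.priors.strict_mixture:
            zc = state.z.astype(float)
            return zc, 1.0 - zc
        one = np.ones(self.N)
        return one, one

    def _xb(self, state):
        if self.p == 0:
            return np.zeros(self.N)
        return self.panel.X @ state.beta

    # -- field updates ----------------------------------------------------
    def _prior_sweep(self, state: ModelState):
        """Ancestral block-Gibbs when the likelihood is disabled: each
        (scale, field) block's conditional factorises as prior(scale) x
        prior(field | scale), so the sweep draws the hierarchy top-down and
        produces exact draws from the joint prior (alpha0 has an improper
        flat prior and is left untouched)."""
        rng = self.rng
        pr = self.priors
        fix = pr.fixed_scales
        hs = pr.halfnormal_scale
        if "sigma_v" not in fix:
            state.sigma_v = abs(rng.standard_normal()) * hs
        if "sigma_h" not in fix:
            state.sigma_h = abs(rng.standard_normal()) * hs
        if "sigma_gamma" not in fix:
            state.sigma_gamma = abs(rng.standard_normal()) * hs
        if "a" not in fix:
            state.a = math.sqrt(pr.a_prior_var) * rng.standard_normal()
        if "b" not in fix:
            state.b = abs(rng.standard_normal()) * pr.b_halfnormal_scale
        if "sigma_ik" not in fix:
            state.log_var_ik = state.a + state.b * rng.standard_normal(self.N)
        if self.spatial.rank > 0:
            coeff = np.zeros(self.N)
            nz = ~self._null
            coeff[nz] = rng.standard_normal(int(nz.sum())) * state.sigma_v / np.sqrt(self._lamR[nz])
            state.v = self._VR @ coeff
        else:
            state.v = np.zeros(self.N)
        state.h = state.v + state.sigma_h * rng.standard_normal(self.N)
        # constrained ICAR draws in the temporal eigenbasis
        coeff = rng.standard_normal(len(self._lamT)) * state.sigma_gamma / np.sqrt(self._lamT)
        state.gamma = self._VT @ coeff
        sig_ik = np.exp(0.5 * state.log_var_ik)
        coeffs = rng.standard_normal((self.N, len(self._lamT))) * (
            sig_ik[:, None] / np.sqrt(self._lamT)[None, :]
        )
        state.K = coeffs @ self._VT.T
        state.u = math.sqrt(pr.u_prior_var) * rng.standard_normal(self.N)
        if self.p:
            state.beta = math.sqrt(pr.beta_prior_var) * rng.standard_normal(self.p)
        return state

    def update_latent_fields(self, state: ModelState, adapt_rate: float):
        if self.priors.likelihood_off:
            return self._prior_sweep(state)
        rng = self.rng
        pr = self.priors
        E = self.panel.E
        y = self.panel.y
        wc, was = self._weights(state)
        xb = self._xb(state)

        eg = np.exp(np.minimum(state.gamma, _EXP_CLIP))
        eh = np.exp(np.minimum(state.alpha0 + state.h + xb, _EXP_CLIP))

        # alpha0 (flat prior)
        lam0 = float(np.sum(wc * E * eh) * eg.sum())
        d = self.steps.alpha0 * rng.standard_normal()
        dll = float(np.sum(wc * self.sy)) * d - lam0 * math.expm1(min(d, _EXP_CLIP))
        acc = math.log(rng.random()) < dll
        if acc:
            state.alpha0 += d
            eh *= math.exp(d)
        self.accept.add("alpha0", acc, 1)
        if adapt_rate:
            self.steps.alpha0 = _adapt(self.steps.alpha0, float(acc), self.settings.target_accept, adapt_rate)

        # h_i, vectorised (conditionally independent across areas)
        c_i = wc * E * np.exp(np.minimum(state.alpha0 + xb, _EXP_CLIP)) * eg.sum()
        d = self.steps.h * rng.standard_normal(self.N)
        hp = state.h + d
        dprior = -((hp - state.v) ** 2 - (state.h - state.v) ** 2) / (2.0 * state.sigma_h**2)
        dll = wc * self.sy * d - c_i * np.expm1(d) * np.exp(np.minimum(state.h, _EXP_CLIP))
        accv = np.log(rng.random(self.N)) < dll + dprior
        state.h = np.where(accv, hp, state.h)
        self.accept.add("h", accv.sum(), self.N)
        if adapt_rate:
            self.steps.h = _adapt(self.steps.h, accv.astype(float), self.settings.target_accept, adapt_rate)

        # v: exact constrained Gibbs draw (Gaussian full conditional)
        self._update_v(state)

        # gamma: even/odd blocked MH (sites of one parity are conditionally
        # independent given the other under the first-order RW prior)
        wsum = float(np.sum(wc * E * np.exp(np.minimum(state.alpha0 + state.h + xb, _EXP_CLIP))))
        cy = (wc[:, None] * y).sum(axis=0)
        sg2 = 2.0 * state.sigma_gamma**2
        acc_n = 0
        for parity in (0, 1):
            idx = np.arange(parity, self.T, 2)
            g = state.gamma[idx]
            d = self.steps.gamma[idx] * rng.standard_normal(len(idx))
            gp = g + d
            dq = np.zeros(len(idx))
            left = idx > 0
            dq[left] += (gp[left] - state.gamma[idx[left] - 1]) ** 2 \
                - (g[left] - state.gamma[idx[left] - 1]) ** 2
            right = idx < self.T - 1
            dq[right] += (gp[right] - state.gamma[idx[right] + 1]) ** 2 \
                - (g[right] - state.gamma[idx[right] + 1]) ** 2
            dll = cy[idx] * d - wsum * (
                np.exp(np.minimum(gp, _EXP_CLIP)) - np.exp(np.minimum(g, _EXP_CLIP))
            )
            accv = np.log(rng.random(len(idx))) < dll - dq / sg2
            state.gamma[idx] = np.where(accv, gp, g)
            acc_n += int(accv.sum())
            if adapt_rate:
                self.steps.gamma[idx] = _adapt(
                    self.steps.gamma[idx], accv.astype(float), self.settings.target_accept, adapt_rate
                )
        self.accept.add("gamma", acc_n, self.T)
        # re-centre gamma, absorb into alpha0
        c = state.gamma.mean()
        state.gamma -= c
        state.alpha0 += c

        # u_i, vectorised
        eK = np.exp(np.minimum(state.K, _EXP_CLIP)).sum(axis=1)
        xb_as = xb if pr.covariates_in_areaspec else np.zeros(self.N)
        base = was * E * np.exp(np.minimum(xb_as, _EXP_CLIP)) * eK
        d = self.steps.u * rng.standard_normal(self.N)
        up = state.u + d
        dprior = -(up**2 - state.u**2) / (2.0 * pr.u_prior_var)
        dll = was * self.sy * d - base * np.expm1(d) * np.exp(np.minimum(state.u, _EXP_CLIP))
        accv = np.log(rng.random(self.N)) < dll + dprior
        state.u = np.where(accv, up, state.u)
        self.accept.add("u", accv.sum(), self.N)
        if adapt_rate:
            self.steps.u = _adapt(self.steps.u, accv.astype(float), self.settings.target_accept, adapt_rate)

        # K: vectorised across areas and across same-parity time points
        sig2_ik = np.exp(state.log_var_ik)
        baseK = was * E * np.exp(np.minimum(state.u + xb_as, _EXP_CLIP))
        accK = 0
        for parity in (0, 1):
            idx = np.arange(parity, self.T, 2)
            k = state.K[:, idx]
            d = self.steps.K[:, idx] * rng.standard_normal((self.N, len(idx)))
            kp = k + d
            dq = np.zeros((self.N, len(idx)))
            left = idx > 0
            if left.any():
                nb = state.K[:, idx[left] - 1]
                dq[:, left] += (kp[:, left] - nb) ** 2 - (k[:, left] - nb) ** 2
            right = idx < self.T - 1
            if right.any():
                nb = state.K[:, idx[right] + 1]
                dq[:, right] += (kp[:, right] - nb) ** 2 - (k[:, right] - nb) ** 2
            dll = y[:, idx] * was[:, None] * d - baseK[:, None] * (
                np.exp(np.minimum(kp, _EXP_CLIP)) - np.exp(np.minimum(k, _EXP_CLIP))
            )
            accv = np.log(rng.random((self.N, len(idx)))) < dll - dq / (2.0 * sig2_ik[:, None])
            state.K[:, idx] = np.where(accv, kp, k)
            accK += int(accv.sum())
            if adapt_rate:
                self.steps.K[:, idx] = _adapt(
                    self.steps.K[:, idx], accv.astype(float), self.settings.target_accept, adapt_rate
                )
        self.accept.add("K", accK, self.N * self.T)
        # re-centre each K row, absorb into u
        c = state.K.mean(axis=1)
        state.K -= c[:, None]
        state.u += c

        # beta_j, scalar MH each (covariates shared across components)
        if self.p:
            self._update_beta(state, wc, was, adapt_rate)

        if not np.isfinite(state.alpha0) or not (
            np.isfinite(state.h).all() and np.isfinite(state.u).all()
            and np.isfinite(state.K).all() and np.isfinite(state.gamma).all()
        ):
            raise McmcError("divergent chain: non-finite latent field")
        return state

    def _update_v(self, state: ModelState):
        """Joint Gibbs draw of v | h, sigma_v, sigma_h on the per-component
        sum-to-zero subspace (conditioning by kriging); singleton components
        are pinned at 0."""
        if self.spatial.rank == 0:
            state.v = np.zeros(self.N)
            return
        # precision in the eigenbasis of R is diagonal: lam/sig_v^2 + 1/sig_h^2
        prec = self._lamR / state.sigma_v**2 + 1.0 / state.sigma_h**2
        b = self._VR.T @ (state.h / state.sigma_h**2)
        w = b / prec + self.rng.standard_normal(self.N) / np.sqrt(prec)
        w[self._null] = 0.0  # sum-to-zero per component; isolated areas at 0
        state.v = self._VR @ w

    def _update_beta(self, state, wc, was, adapt_rate):
        rng = self.rng
        pr = self.priors
        E = self.panel.E
        xb = self._xb(state)
        eg_sum = np.exp(np.minimum(state.gamma, _EXP_CLIP)).sum()
        baseC = wc * E * np.exp(np.minimum(state.alpha0 + state.h, _EXP_CLIP)) * eg_sum
        eKsum = np.exp(np.minimum(state.K, _EXP_CLIP)).sum(axis=1)
        baseAS = was * E * np.exp(np.minimum(state.u, _EXP_CLIP)) * eKsum
        sy = self.sy
        acc_n = 0
        for j in range(self.p):
            d = self.steps.beta[j] * rng.standard_normal()
            xj = self.panel.X[:, j]
            xb_new = xb + xj * d
            exb, exb_new = (
                np.exp(np.minimum(xb, _EXP_CLIP)),
                np.exp(np.minimum(xb_new, _EXP_CLIP)),
            )
            dll = float(np.sum(wc * sy * xj) * d - np.sum(baseC * (exb_new - exb)))
            if pr.covariates_in_areaspec:
                dll += float(np.sum(was * sy * xj) * d - np.sum(baseAS * (exb_new - exb)))
            bp = state.beta[j] + d
            dprior = -(bp**2 - state.beta[j] ** 2) / (2.0 * pr.beta_prior_var)
            ok = math.log(rng.random()) < dll + dprior
            if ok:
                state.beta[j] = bp
                xb = xb_new
                acc_n += 1
            if adapt_rate:
                self.steps.beta[j] = _adapt(self.steps.beta[j], float(ok), self.settings.target_accept, adapt_rate)
        self.accept.add("beta", acc_n, self.p)

    # -- scale updates ----------------------------------------------------
    def update_scales(self, state: ModelState, adapt_rate: float):
        if self.priors.likelihood_off:
            return state  # scales drawn jointly with the fields in _prior_sweep
        rng = self.rng
        pr = self.priors
        fix = pr.fixed_scales
        ta = self.settings.target_accept

        def mh_log_scale(cur, step, logpost, name):
            lcur = math.log(cur)
            lprop = lcur + step * rng.standard_normal()
            prop = math.exp(lprop)
            # + Jacobian of the log transform (lprop - lcur)
            dlp = logpost(prop) - logpost(cur) + (lprop - lcur)
            ok = np.isfinite(dlp) and math.log(rng.random()) < dlp
            self.accept.add(name, ok, 1)
            return (prop if ok else cur), ok

        hs = pr.halfnormal_scale

        if "sigma_h" not in fix:
            S = float(np.sum((state.h - state.v) ** 2))

            def lp_h(s):
                return -(s**2) / (2 * hs**2) - self.N * math.log(s) - S / (2 * s**2)

            state.sigma_h, ok = mh_log_scale(state.sigma_h, self.steps.lsig_h, lp_h, "sigma_h")
            if adapt_rate:
                self.steps.lsig_h = _adapt(self.steps.lsig_h, float(ok), ta, adapt_rate)

        if "sigma_v" not in fix:
            rank = self.spatial.rank
            qv = float(state.v @ (self.R_spatial @ state.v)) if rank else 0.0

            def lp_v(s):
                return -(s**2) / (2 * hs**2) - rank * math.log(s) - qv / (2 * s**2)

            state.sigma_v, ok = mh_log_scale(state.sigma_v, self.steps.lsig_v, lp_v, "sigma_v")
            if adapt_rate:
                self.steps.lsig_v = _adapt(self.steps.lsig_v, float(ok), ta, adapt_rate)

        if "sigma_gamma" not in fix:
            qg = float(np.sum(np.diff(state.gamma) ** 2))
            rank = self.T - 1

            def lp_g(s):
                return -(s**2) / (2 * hs**2) - rank * math.log(s) - qg / (2 * s**2)

            state.sigma_gamma, ok = mh_log_scale(state.sigma_gamma, self.steps.lsig_g, lp_g, "sigma_gamma")
            if adapt_rate:
                self.steps.lsig_g = _adapt(self.steps.lsig_g, float(ok), ta, adapt_rate)

        if "sigma_ik" not in fix:
            # vectorised MH on log variances; (T-1)/2 power from the ICAR
            # kernel of each K row
            qk = np.sum(np.diff(state.K, axis=1) ** 2, axis=1)
            lv = state.log_var_ik
            d = self.steps.lv * rng.standard_normal(self.N)
            lvp = lv + d

            def lp_lv(x):
                return (
                    -((x - state.a) ** 2) / (2 * state.b**2)
                    - 0.5 * (self.T - 1) * x
                    - qk / (2 * np.exp(x))
                )

            accv = np.log(rng.random(self.N)) < lp_lv(lvp) - lp_lv(lv)
            state.log_var_ik = np.where(accv, lvp, lv)
            self.accept.add("log_var_ik", accv.sum(), self.N)
            if adapt_rate:
                self.steps.lv = _adapt(self.steps.lv, accv.astype(float), ta, adapt_rate)

        if "a" not in fix:
            # Normal-Normal conjugacy given the N log-variances
            prec = self.N / state.b**2 + 1.0 / pr.a_prior_var
            mean = float(np.sum(state.log_var_ik)) / state.b**2 / prec
            state.a = mean + rng.standard_normal() / math.sqrt(prec)

        if "b" not in fix:
            S = float(np.sum((state.log_var_ik - state.a) ** 2))
            bs = pr.b_halfnormal_scale

            def lp_b(x):
                return -(x**2) / (2 * bs**2) - self.N * math.log(x) - S / (2 * x**2)

            state.b, ok = mh_log_scale(state.b, self.steps.lb, lp_b, "b")
            if adapt_rate:
                self.steps.lb = _adapt(self.steps.lb, float(ok), ta, adapt_rate)

        return state

    # -- one full sweep ----------------------------------------------------
    def sweep(self, state: ModelState, it: int) -> ModelState:
        adapt_rate = 0.0
        if self.settings.adapt and it < self.settings.n_burnin:
            adapt_rate = min(0.25, (it + 1) ** -0.6)
        state = self.update_latent_fields(state, adapt_rate)
        state = self.update_scales(state, adapt_rate)
        state.z = gibbs_update_z(state, self.panel, self.priors, self.rng)
        return state


def initial_state(
    panel: SpaceTimePanel, priors: PriorConfig, rng: np.random.Generator
) -> ModelState:
    """Dispersed start: alpha0 near the crude log rate, fields jittered
    around 0, scales at 0.5, all areas initially in the Common Model."""
    N, T = panel.y.shape
    crude = math.log(max(panel.y.sum(), 1) / (T * panel.E.sum()))
    fix = priors.fixed_scales
    return ModelState(
        alpha0=crude + 0.1 * rng.standard_normal(),
        h=0.1 * rng.standard_normal(N),
        v=np.zeros(N),
        gamma=np.zeros(T),
        u=crude + 0.1 * rng.standard_normal(N),
        K=np.zeros((N, T)),
        z=np.ones(N, dtype=np.int8),
        sigma_h=fix.get("sigma_h", 0.5),
        sigma_v=fix.get("sigma_v", 0.5),
        sigma_gamma=fix.get("sigma_gamma", 0.5),
        log_var_ik=np.full(N, 2 * math.log(fix.get("sigma_ik", 0.5))),
        a=fix.get("a", 0.0),
        b=fix.get("b", 1.0),
        beta=np.zeros(panel.n_covariates),
    )


_STORE = (
    "alpha0", "h", "v", "gamma", "u", "K", "z",
    "sigma_h", "sigma_v", "sigma_gamma", "log_var_ik", "a", "b", "beta",
)


def run_mcmc(
    panel: SpaceTimePanel,
    graph: SpatialGraph,
    priors: PriorConfig | None = None,
    settings: McmcSettings | None = None,
    store: tuple = _STORE,
) -> PosteriorSamples:
    """Run independent chains, discard burn-in, thin, and collect draws.

    Chain c gets its own RNG stream spawned from ``settings.seed``; two runs
    with the same settings are bitwise identical.
    """
    priors = priors or PriorConfig()
    settings = settings or McmcSettings()
    if graph.n_areas != panel.n_areas or tuple(graph.labels) != tuple(panel.area_labels):
        raise McmcError("spatial graph areas do not match panel areas")
    spatial = icar_structure(graph)
    temporal = icar_structure(build_temporal_graph(panel.n_times))
    N, T, p = panel.n_areas, panel.n_times, panel.n_covariates

    n_stored = settings.n_stored
    shapes = {
        "alpha0": (), "h": (N,), "v": (N,), "gamma": (T,), "u": (N,),
        "K": (N, T), "z": (N,), "sigma_h": (), "sigma_v": (),
        "sigma_gamma": (), "log_var_ik": (N,), "a": (), "b": (), "beta": (p,),
    }
    draws = {
        name: np.empty((settings.n_chains, n_stored) + shapes[name],
                       dtype=np.int8 if name == "z" else float)
        for name in store
    }

    ss = np.random.SeedSequence(settings.seed)
    children = ss.spawn(settings.n_chains)
    chain_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    acceptance = {}
    for c in range(settings.n_chains):
        rng = np.random.Generator(np.random.PCG64(children[c]))
        runner = _ChainRunner(panel, spatial, temporal, priors, settings, rng)
        state = initial_state(panel, priors, rng)
        kept = 0
        for it in range(settings.n_iter):
            try:
                state = runner.sweep(state, it)
            except McmcError as err:
                raise McmcError(
                    f"chain {c} aborted at iteration {it}: {err}; "
                    f"alpha0={state.alpha0!r}, sigma=({state.sigma_h}, "
                    f"{state.sigma_v}, {state.sigma_gamma})"
                ) from err
            if it == settings.n_burnin - 1:
                # report acceptance rates for the frozen (post-adaptation) kernel
                runner.accept = _AcceptLog()
            if it >= settings.n_burnin and (it - settings.n_burnin) % settings.thin == 0:
                if kept < n_stored:
                    for name in draws:
                        draws[name][c, kept] = getattr(state, name)
                    kept += 1
            if settings.progress_every and (it + 1) % settings.progress_every == 0:
                log.info("chain %d: %d/%d iterations", c, it + 1, settings.n_iter)
        for k, r in runner.accept.rates().items():
            acceptance.setdefault(k, []).append(r)
    acceptance = {k: float(np.mean(v)) for k, v in acceptance.items()}

    return PosteriorSamples(
        draws=draws,
        settings=settings,
        priors=priors,
        area_labels=tuple(panel.area_labels),
        time_labels=tuple(panel.time_labels),
        covariate_names=tuple(panel.covariate_names),
        acceptance=acceptance,
        chain_seeds=chain_seeds,
    )
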