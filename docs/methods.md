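# Methods

## The model

The package fits a hierarchical Poisson mixture to an area × month count
panel. Level one is the likelihood `Y_it ~ Poisson(mu_it * E_i)`, where the
expected count `E_i` is a time-constant offset: the events area `i` would
record per month if pooled age-sex-specific reference rates applied to its
population. Level two mixes two log-linear predictors through a latent
binary indicator `z_i`:

- **Common Model** `alpha0 + h_i + gamma_t (+ x_i'beta)`: one spatial
  surface and one national temporal trend shared by all areas; on the log
  scale every usual area is a parallel shift of the national curve.
- **Area-Specific Model** `u_i + k_it (+ x_i'beta)`: an area intercept and a
  free per-area temporal field, unconstrained by the national trend.

Level three is the prior block: `v ~ ICAR(W, sigma_v^2)` on the binary
area adjacency, `h_i ~ N(v_i, sigma_h^2)` (the BYM convolution),
`gamma ~ ICAR(Q, sigma_gamma^2)` on the month path (a first-order random
walk), `k_i. ~ ICAR(Q, sigma_ik^2)` per area, `u_i ~ N(0, 1000)`,
`alpha0` flat, half-Normal(0,1) on `sigma_h, sigma_v, sigma_gamma`,
`z_i ~ Bernoulli(pi)` with `pi = 0.95`, and the pooling layer
`log(sigma_ik^2) ~ N(a, b^2)` with `a ~ N(0, 1000)` and `b` half-Normal(2.5).
The pooling layer is what makes detection work: with most areas usual, `a`
is driven low, the `k` fields of usual areas are shrunk toward flatness,
and the Area-Specific likelihood gains little over the Common one except
where a genuine deviation exists. A Normal prior on a *variance* parameter
is not well defined, so the 2.5-scale prior is placed half-Normal on the
standard deviation `b`.

Classification: the posterior mean of `z_i`, pooled over chains, is the
probability that area `i` follows the common pattern; areas with
`p_i <= 0.05` are reported unusual, ranked ascending in `p_i` with ties
broken by area label. This is a plain per-area threshold; no false-discovery
adjustment is applied (with a 0.95 prior weight and few expected positives,
the threshold is already conservative).

## Mixture feedback: the cut

The sampler's default follows the two-model "cut" structure: **both**
components are fitted to the full data at every iteration, and `z_i` is a
Gibbs draw from the two per-area predictive likelihoods,
`p_i = pi L_i^C / (pi L_i^C + (1 - pi) L_i^AS)`, computed in log space. This
avoids the trans-dimensional degeneracy of a strict mixture, where the
inactive component's fields drift under their prior and can never win back
the indicator. The strict mixture (each area's likelihood contributing only
to its active component) is available as `PriorConfig(strict_mixture=True)`
for comparison. Covariates enter both component predictors identically
(one shared `beta`); `PriorConfig(covariates_in_areaspec=False)` confines
them to the Common Model.

## Sampler

One sweep of the Metropolis-within-Gibbs kernel:

1. `alpha0`, `h`, `gamma`, `u`, `K`, `beta`: single-site adaptive
   random-walk MH. Sites that are conditionally independent are updated in
   one vectorised block (all `h_i`; all `u_i`; all areas at the even time
   points, then the odd ones, for `gamma` and `K`, since the random-walk
   prior only couples adjacent months).
2. `v`: its full conditional given `h` is Gaussian with precision
   `R/sigma_v^2 + I/sigma_h^2`, diagonal in the eigenbasis of the structure
   matrix `R`; the per-component sum-to-zero constraints are exactly the
   null directions of `R`, so the constrained draw zeroes those coefficients
   — an exact joint Gibbs step, no tuning.
3. Scales: MH on the log scale (with Jacobian) against half-Normal priors;
   the `log sigma_ik^2` vector is updated in one vectorised MH block; `a`
   is a conjugate Normal draw; `b` is log-scale MH.
4. `z`: Gibbs from the two predictive likelihoods.

Identifiability. ICAR priors are improper (constant per connected
component), so after every sweep `gamma` is re-centred with the mean
absorbed into `alpha0`, and each `K` row is re-centred with the mean
absorbed into `u_i`; `v` lives on the per-component sum-to-zero subspace by
construction of the constrained draw, and an isolated area (an island with
no neighbours) has its structured effect pinned at 0, its variation carried
by the unstructured part of the convolution. The ICAR log-kernel exponent
uses rank(R) = n − (number of components).

Adaptation. Per-site step sizes follow a bounded Robbins–Monro recursion
toward 0.44 acceptance during burn-in only, then freeze, so the post-burn-in
kernel satisfies detailed balance. Steps are clipped to [1e-4, 10]: a
flat-prior scalar with no likelihood (e.g. `alpha0` in prior-recovery mode)
accepts every proposal and would otherwise inflate its step without bound.

Initial values: `alpha0` at the crude log standardised rate plus jitter,
fields at 0 plus N(0, 0.1²) jitter, scales at 0.5, all `z_i = 1`; each
chain has its own RNG stream spawned from the run seed, and a run is
bitwise reproducible given its settings.

Prior-recovery mode. With `PriorConfig(likelihood_off=True)` each
(scale, field) block's conditional factorises as prior(scale) ×
prior(field | scale), so the sweep draws the hierarchy ancestrally and
yields exact iid draws from the joint prior. This is what the
prior-recovery tests sample from; the likelihood-on path is pure MH.

Numerical guards: exponent arguments in rate computations are capped at 50
(beyond that the Poisson term is effectively impossible and an `inf` would
poison the MH ratio); a log-likelihood evaluated at an overflowing rate
returns −inf, never NaN; a non-finite latent state aborts the chain with a
diagnostic message.

## Defaults and the run protocol

`McmcSettings()` echoes the production protocol: 3 chains × 80,000
iterations, 20,000 burn-in, thinning 5 → 12,000 stored draws per chain.
Tests and the acceptance script use reduced settings (2–3 chains of
4,000–20,000 iterations depending on problem size) — the package's own
choice of demonstration scale; posterior `z` probabilities stabilise long
before the slowest hyper-parameter (`b`) passes the R-hat gate, which is
why short demonstration runs may carry the advisory "diagnostics failed"
stamp while detecting correctly.

Convergence is summarised by the classic split-chain potential scale
reduction factor (no rank-normalisation), batch-means Monte Carlo standard
error (default batch size ⌊√n⌋), and the batch-means effective sample size
var/mcse². The monitored set defaults to `alpha0`, all scales, `a`, `b`,
every `gamma_t`, 10 fixed-seed-sampled `h_i` and `u_i`, and any `beta`;
full-field monitoring is available by passing an explicit list. Posterior
intervals are 95% equal-tailed with linear-interpolation quantiles; the
exp/quantile commutation property therefore holds to numerical precision
rather than exactly (interpolation happens on the transformed scale).

## Expected counts and covariates

Reference rates are pooled over the whole study region
(`rate_g = events_g / persons_g` per age-sex stratum) and applied to each
area's population: `E_i = Σ_g n_ig rate_g`, optionally divided by the
number of months so the offset is per time point — with internally derived
rates this conserves the national total (`Σ_i E_i · T` = total events,
tested to 1e-6 relative). `E_i` is deliberately time-constant: all
seasonality is carried by `gamma_t` (and `k_it` for unusual areas). Areas
with zero population get `E_i = 0` and are excluded from modelling with a
warning rather than crashing on `log 0`. Age bandings are user-defined; the
synthetic generator uses 5-year bands to 85+. Area covariates: percent of
persons in a configurable set of "active" bands, the male:female ratio, and
rank-based quintile dummies of a deprivation-type score (equal-count groups,
remainder assigned to lower quintiles first, lowest quintile as reference).
Covariate columns are mean-centred before sampling, with the centring
constants stored.

## The synthetic-data generator

The generator emulates the structure of the motivating surveillance
setting: by default 211 areas on an irregular planar adjacency (Delaunay
triangulation of random points; a rook-adjacency grid is available), 8
monthly time points, expected counts uniform on [100, 500] events per
area-month, a smooth spatial surface (`sigma_v = 0.3`, `sigma_h = 0.15`),
and a national trend built from a deterministic seasonal bump of amplitude
0.4 on the log scale peaking at the fifth month (a December analogue for an
August-to-March window) plus ICAR noise (`sigma_gamma = 0.05`). These
magnitudes are stylised — chosen to give a clearly estimable seasonal trend
at realistic surveillance count sizes — not calibrated to any proprietary
prescription, admission or mortality series.

Unusual areas are injected by replacing the common trend with a centred
deviation from a four-shape menu mirroring the qualitative patterns such
surveillance studies report: `flat` (no seasonality — an intervention that
suppressed the epidemic signal), `shifted_peak` (the seasonal curve rotated
by a stated month offset), `ramp` (monotone drift with total rise equal to
the stated magnitude), and `spike` (the common trend plus a one-month
excursion, by default at the trend's minimum). The default magnitude 0.7 on
the log scale (≈ 2× risk for one month) was fixed as the generator's
"strong deviation" regime by a pilot power calculation targeting ≳80%
detection at T = 8; it is a study condition, not a tuning knob. Injected
areas keep their spatial level (`alpha0 + h_i`) so detection cannot key on
level differences, only on trend shape. Ground truth (all latent fields,
indicators, deviating trends) is returned alongside the panel and
exportable to JSON; each pipeline stage draws from a named RNG substream of
the config seed so stages are replayable in isolation.

What the generator does **not** emulate: real administrative geography and
population sizes, overdispersion beyond Poisson, data-quality artefacts
(late registrations, coding changes), within-area age-sex trend
interactions, or correlated multi-source outcomes. Passing tests therefore
demonstrate the method's statistical behaviour under its own assumptions at
surveillance-like scale, not performance on any particular real dataset.

## Verification highlights

The test suite checks, among other things: graph/ICAR identities against
brute-force enumeration; standardisation against hand-computed quotients
and the conservation identity; prior recovery at n = 10⁴ iid draws
(Kolmogorov–Smirnov at α = 0.01 for the half-Normal scales, an exact
binomial test for the Bernoulli(0.95) indicator); agreement of the MCMC
posterior `P(z_i = 1)` with a brute-force grid-integration posterior on a
2-area × 2-month instance with fixed scales (within ±0.02); recovery of
the national trend (95% CI covers ≥ 6/8 months in ≥ 90% of 20 seeded
100-area panels) and of the spatial surface (Pearson r > 0.8 between
posterior-mean `exp(h_i)` and truth); detection sensitivity ≥ 0.8 with ≤ 1
false flag per 100-area null panel at the 0.05 rule (20 signal + 20 null
panels); mixture degeneracy at `pi = 1` and `pi = 0`; and the split-chain
R-hat against an independent reference implementation.

## Known limitations

- Time complexity is O(N·T) per sweep plus one N×N eigen-solve per chain
  setup and an O(N²) matrix-vector product per sweep for the spatial layer;
  dense spatial algebra is comfortable to a few hundred areas but not
  designed for N in the tens of thousands.
- `E_i` is time-constant by design; strong within-window population shifts
  would be absorbed by the temporal fields.
- The slowest-mixing parameter is the hyper-sd `b`; short chains can leave
  its R-hat above 1.1 while detection probabilities are already stable. The
  advisory gate reports this rather than blocking the report.
- Missing cells in the count panel are rejected, not imputed.
- Change-point timing (when an unusual pattern starts) is not estimated;
  the model flags areas, not months.
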