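# Methods

## The inverse problem

`vitalrecon` reconstructs size- and time-dependent vital rates —
survival, growth, fecundity and offspring size — for a population whose
environment changes directionally (land degradation, chronic
disturbance, succession, climate trends), using only *static*,
population-level data: at a handful of observation years, the log-sizes
of the sampled individuals and the population density (individuals per
unit area). No individual is ever followed between years. The premise is
that a time series of size structures and densities carries the imprint
of the changing vital rates, so the rates can be recovered by asking
which rate functions, when projected forward, reproduce the observed
series best.

## Population model

The population is described by a time-varying integral projection model
(IPM) on log-size `x`:

    n(y, t+1) = ∫ k(y, x, t) n(x, t) dx,
    k(y, x, t) = s(x, t) g(y | x, t) + f1(x, t) f2(y, t)

with `n(x, t)` the density of individuals over log-size. The four vital
rates each follow a linear predictor in size, time and their interaction,

    η(x, t) = a0 + a1 x + a2 t + a3 x t

on a link scale chosen per rate:

| rate | link | extra parameters | block size |
|------|------|------------------|-----------|
| survival `s` | logit | — | 4 |
| growth mean `E[y|x]` | identity | residual SD `σ_g > 0` | 5 |
| newborn count `f1` | log | — | 4 |
| newborn size mean | identity (no `x` term) | SD `σ_f > 0` | 3 |

Newborn size cannot depend on parent size because fecundity factorises
as `f1(x,t)·f2(y,t)`. This gives 16 free scalars. The
`bounded_survival` variant multiplies the logistic survival by a
time-varying asymptote `s_max(t) = [1 + exp(β1 + β2 t)]⁻¹` (18 scalars),
preventing effectively immortal large individuals — important for
long-lived species such as globose cacti. The exact functional forms
are this package's documented convention; any forms capturing the key
size/time responses could be substituted behind the same interface.

### Discretisation

Midpoint rule on `N` equal cells over `[L, U]` (defaults `[0, 5]` in
log-size units with `N = 50`, the resolution used throughout the
validation protocols; doubling the resolution changes the composite
log-likelihood by ~1e-3 relative, well below sampling noise, so finer
meshes buy accuracy only for very narrow growth spreads).
Probability mass of `g` or `f2` falling outside `[L, U]` ("eviction")
is returned by truncate-and-renormalise: every growth column and the
newborn-size vector are divided by their discrete within-mesh mass, so
survivors and newborn counts are conserved exactly (to 1e-9 per
projection step in the conservation test). Columns whose mass
underflows (mean far outside the mesh, tiny spread) degenerate to a
point mass in the nearest boundary cell.

The one-year operator is the matrix-vector product with
`K(t)[i,j] ≈ k(y_i, x_j, t)·h`; kernels are re-evaluated at every
integer year. Observation times are snapped to integer years.

### Initialisation

Projection starts at the first observation year from the *stable*
(asymptotic) size structure of `K(t0)` — the natural assumption when the
environment was constant before observations began. The stable
structure is computed by power iteration (L1-normalised, tolerance
1e-10, at most 10,000 iterations) with a dense eigendecomposition as a
fallback for degenerate spectra; a relative residual above 1e-8 raises a
diagnostic error. Because the model is linear in `n`, the absolute
density at `t0` (`scale0`) is not determined by the kernel; see below.

## Composite likelihood

At each observation year there are many size data but a single density
datum, so the criterion weights the two:

    l = l_n + w · l_d

- `l_n`: observed log-sizes are treated as i.i.d. draws from the
  predicted structure normalised to a probability density over the mesh
  (the natural point-process likelihood for a random sample of
  individuals). The density is interpolated linearly between nodes:
  piecewise-linear evaluation keeps `l_n` smooth in the parameters and
  is second-order accurate in the mesh width, which the cell-constant
  alternative is not. Sizes outside the mesh are clipped to the nearest
  cell; a clip fraction above 5 % triggers a warning to widen the mesh.
- `l_d`: observed densities are lognormal around the predicted density,
  parameterised by the *arithmetic* mean with log-scale `σ_d`
  (default 0.3), mirroring the generator's noise model. Zero observed
  densities carry no information under a lognormal error and are
  skipped with a warning.
- `w` sweeps {0, 1, 10, 100, 1000}. Small nonzero values usually work
  best: `w = 0` ignores the density signal entirely, very large values
  overfit density sampling error.

`scale0` enters only `l_d` and multiplicatively, so its ML value under
the lognormal model has a closed form (the geometric mean of
observed/predicted ratios times `exp(σ_d²/2)`) and is profiled out
rather than optimised. `σ_d` is fixed, not profiled — jointly profiling
scale and spread degenerates (`σ_d → 0`) whenever the densities can be
matched exactly.

## Estimation protocol

The likelihood surface is multimodal: different vital-rate combinations
produce nearly identical observable series. The protocol is therefore
multi-start bounded maximisation — L-BFGS-B with finite-difference
gradients inside the box given by per-parameter intervals — from either
perturbed reference values (each scalar multiplied by `1 + ε`, `ε`
uniform within ±0/5/10/25/50 %; the default plan of 1 exact + 4×10
perturbed starts gives 41 starting sets) or uniform random draws within
the intervals, for every `w` in the sweep. Optimisation runs on the
unit box (each parameter standardised by its interval), which also
fixes the conditioning problem of per-year time slopes being ~100×
smaller than intercepts; results are reported on the natural scale.
Runs that cannot start (−∞ likelihood) are logged and counted — with
poor starts this happens more often, which is itself a diagnostic.
Each run returns the best point seen, so its likelihood never falls
below the start's.

Converged runs are grouped into distinct solutions per weight: two fits
share a solution when their interval-standardised parameter vectors
differ by < 0.05 (sup norm) and their likelihoods by < 1.0 — tight
enough to separate genuinely distinct optima without splitting
optimiser jitter. Clustering is greedy on likelihood-sorted fits and
hence independent of input order.

### Solution selection and plausibility

Goodness of fit alone cannot rank the competing optima, so solutions
are screened with coarse biological knowledge (`PlausibilityRules`):
the expected sign of the size–survival and size–fecundity relations
(+, −, "none expected", or unconstrained) and an admissible ceiling on
seedling survival. Sign rules act on the standardised size slope of the
fitted surface (a violation when the sign is wrong, or when its
magnitude exceeds 0.5 under a "none expected" rule); the seedling rule
checks survival at the smallest mesh node across years. Solutions
violating a rule are labelled `type1` and discarded; plausible-but-wrong
(`type2`) optima are undetectable without ground truth, so the label is
advisory. The working solution is the best-likelihood plausible cluster
head at the smallest productive nonzero `w`, falling back to `w = 0`
and finally to the overall best fit.

### Identifiability caveat

Even with exhaustive noise-free samples the likelihood carries
near-flat ridges along compensating parameter directions (e.g. trading
survival intercept against survival size-slope): single scalars can
drift several percent of their interval at a likelihood cost below one
log-unit, while the implied vital-rate *surfaces* stay fixed. Recovery
is therefore asserted and reported at the level of the surfaces
(`r_s`, `r_g`, `r_f`) and densities (`r_d`), not raw coefficients.

## Accuracy metrics

Against a known truth, recovery is scored by Pearson correlations over
a size × time grid (50 sizes × every integer year in the observation
window): `r_s` and `r_f` on the survival and newborn-count surfaces,
`r_g` on the growth conditional-mean surface (correlating full
conditional densities is not Pearson-shaped), plus `r_d` between
reconstructed and observed densities at the observation times
(undefined below 3 times). Their arithmetic mean `r_m` is the overall
score; `r_m ≥ 0.9` is read as an essentially correct reconstruction.
If both surfaces are constant the correlation is defined as 1; if
exactly one is constant, as 0 with a flag.

## Synthetic data generator

The generator emulates a sparse field protocol and provides ground
truth for validation:

1. Per-parameter intervals wide enough that every rate can increase,
   decrease or ignore size and time (`data/default_intervals.json`,
   this package's own calibration).
2. A species drawn uniformly within the intervals, rejected unless its
   century of densities stays within [1, 5·10⁴] individuals per unit
   area starting from 200 (≈20 % of draws pass; 100 consecutive
   rejections raise an error). Populations outside that band would have
   gone extinct or be unsampleable, and could not appear in data.
3. A deterministic trajectory over years 1–100 from the stable
   structure at year 1, initial density 200.
4. 10 distinct observation years drawn uniformly without replacement
   from 1–100.
5. Per year: a sampled count, lognormal with arithmetic mean equal to
   density × effort (effort 1, `σ_c = 0.3` by default — the generator's
   one free noise knob), rounded; then that many log-sizes by
   inverse-CDF draws from the year's piecewise-constant structure.

What the generator does *not* emulate: measurement error on individual
sizes, demographic stochasticity, environmental fluctuation around the
trend, spatial sampling structure, and chronosequence artefacts
(site-to-site differences, disturbance-index error). Passing recovery
tests therefore show that sparse noisy samples of the *modelled*
process identify the rates — not that the model is robust to violations
of its own assumptions.

## Chronosequence utility

For space-for-time designs, observation "times" come from a
disturbance index assumed to accumulate linearly: resurveying sites
after `Δt` years gives the annual rate as the mean index change divided
by `Δt`, and each site's time since onset is its index over that rate.
A non-positive rate (no directional trend) is an error.

## Validation experiments and problem sizes

`vitalrecon.protocols` packages the standard experiments, both run on
the `N = 50` mesh:

- `recovery_experiment`: one species, one noisy dataset, multi-start
  sweep over all five weights, coarse sign rules derived from the true
  species, `r_m` of the selected solution. The package's replicated
  runs reach `r_m ≥ 0.9` in the large majority of seeds; `w = 1`
  usually wins, and very large `w` visibly degrades the reconstruction.
- `robustness_trend`: one species, five starts per error level at
  `w = 1`; the fraction of runs with `r_m ≥ 0.9` as a function of
  starting error. The exact start is deterministic, so one run stands
  for its replicates.

`scripts/acceptance.py` runs `recovery_experiment` with one start per
error level (0–50 %) and all five weights — 25 local fits, a few
minutes on one CPU.

## Numerical choices and degenerate inputs

- Fecundity log-link predictor capped at 30 (`exp(30) ≈ 10¹³`) with a
  logged warning.
- Zero kernels: stable structure returns a uniform structure with
  growth rate 0 (the trajectory then collapses to zero density).
- Optimiser failures inside a run (−∞ likelihood, projection failure)
  are penalised, not raised; a run whose *start* is −∞ is reported as
  failed.
- All randomness flows through explicit `numpy.random.Generator` seeds;
  fixed seeds give byte-identical datasets and deterministic fits.

## Known limitations

- Deterministic environment: no year-to-year stochasticity in rates.
- No density dependence; the model is linear in `n`.
- The vital-rate forms are low-order polynomials on link scales; sharply
  nonlinear true rates would be mis-specified (use the bounded-survival
  variant when saturating survival matters).
- Alternative (type-2) solutions can survive screening; without
  independent demographic knowledge the selected solution is a working
  hypothesis, not a certainty.
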