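# Methods notes

## Model

A four-state dynamic occupancy model with state-uncertain detection — a
hidden Markov model whose hidden chain is each territory's seasonal state
(1 unoccupied, 2 single, 3 pair, 4 reproducing pair) and whose emissions are
visit-level observed states. Assumptions:

- **Within-season closure.** The true state is constant within a season;
  visits within a season are conditionally independent given the state.
  Consequently the likelihood is invariant to visit order within a season
  (property-tested).
- **Classification constraint.** An observed state can never exceed the true
  state: the DPM satisfies p[m,n] = 0 for n > m, and row 1 is (1,0,0,0).
  Imputed states therefore always dominate their observations.
- **Markov dynamics with exchangeable year effects.** Season-specific
  transition and detection effects are draws from normal hyper-distributions
  with estimated means and SDs. Years borrow strength; there is no built-in
  temporal trend in the parameters (trends are estimated *post hoc* from
  imputed state counts).
- **Block separation.** Every parameter varies by block; blocks are fitted
  independently.
- **No covariates** on transitions or initial state probabilities; detection
  varies with standardized Julian date through linear and quadratic terms.

Territories are modelled over their block's full season range. Seasons in
which a territory has no visits contribute transition factors but no
detection factors; territories that enter the survey program late are treated
as latent-only before their first visit. This is one defensible choice for
staggered entry — conditioning each territory's chain on its own first survey
year is the main alternative — and it slightly widens early-season count
intervals for late-entry territories.

## Prior conventions

The hyper-mean prior "N(0, 2)" is read as **variance 2** (SD √2 ≈ 1.414),
matching the BUGS/JAGS `dnorm(mean, precision)` convention with precision
0.5; `PriorSpec(mean_prior_scale_is_variance=False)` switches to SD 2. The
"Gamma(2, 0.5)" prior is shape 2, **rate** 0.5 (mean 4), placed on the
random-effect **SD**; `PriorSpec(sd_prior_on="variance")` moves it to σ².
These switches exist because the two conventions are easily conflated and
both are defensible; defaults are stated here and in the docstrings.

## Sampler

Blocked Gibbs (numba-compiled, `msodyn._kernel`), per sweep:

1. detection log-likelihood table L[i,t,m] from current coefficients;
2. exact FFBS draw of each territory's trajectory (forward pass normalized
   per season; backward categorical sampling);
3. conjugate Dirichlet update of φ₀ from first-season states;
4. per-(season, origin-state) random-walk Metropolis on the 3-vector of
   transition effects, using the latent transition counts (multinomial
   likelihood + normal prior);
5. conjugate normal updates of transition hyper-means; Metropolis on log σ
   with the gamma prior (Jacobian included);
6. per-(season, true-state) Metropolis on the detection coefficient block
   (up to 9 coefficients), using that season's visits at territories
   currently imputed in that state;
7. detection hyperparameters as in 5.

Proposal scales adapt by Robbins–Monro toward acceptance 0.234 (vector
blocks) / 0.44 (scalars) **during burn-in only** and are frozen afterwards,
so retained draws come from a fixed-kernel chain targeting the exact
posterior. Chains are seeded via `numpy.random.SeedSequence(seed)`; runs are
bit-reproducible. Multi-logit and forward computations are log-sum-exp
stabilized, so effects of magnitude hundreds (possible under the vague
hyper-SD prior) do not overflow.

Correctness evidence computed by the test suite: FFBS path frequencies match
exhaustive enumeration of p(z | y, θ) (χ², 10⁴ draws); the forward-algorithm
marginal likelihood matches path enumeration to 10⁻¹⁰; and a run with zero
visits reproduces the joint prior (hyper-means mean ≈ 0, SD ≈ √2; hyper-SD
mean ≈ 4; φ₀ uniform) — a whole-sampler check that the Gibbs kernel has the
intended stationary distribution.

Default chain settings (3 × 55,000, burn-in 5,000, thinning 1/100 → 1,500
retained draws) correspond to the full monitoring-study protocol. The
convergence diagnostic is the classic Gelman–Rubin potential scale reduction
factor on retained draws (split-chain variant available; both verified
against arviz). Reduced runs routinely trip the R-hat > 1.1 warning on weakly
identified hyper-SDs; the warning carries the diagnostic table rather than
failing the fit.

## Synthetic data

`msodyn.simulate.generate` draws season effects from the hyper-distributions,
propagates latent states, then draws visit counts (distribution over 1–15
with median 3, mean ≈ 3.5), visit dates (uniform on day 60–243 by default, an
April–June mode optional), and observations from the DPM at pooled-
standardized dates. `mendocino_preset()` reproduces the 104-territory
three-block design (18/62/24; block C truncated at 2006).

Default "true" hyperparameters are **synthetic**: chosen once so that all
four states occur at non-negligible frequency, detection is strongest for
reproducing pairs and weak (≲ 0.25 per visit) for single owls, and occupied
states persist across years. Features of real monitoring data the generator
does **not** emulate: staggered territory entry/exit (every territory is
surveyed every season, so ~104 territories/year rather than the ~67 of a real
program with turnover), clustering of visit dates around protocol milestones,
observer effects, and any barred-owl or habitat covariates. Passing tests on
synthetic data therefore demonstrate correctness of the machinery under the
model's own assumptions, not robustness to these violations.

Two purpose-built configurations support verification studies:

- `prior_predictive_config` draws the *true* hyperparameters from the model's
  priors, the design under which 90% credible intervals must cover truth at
  exactly 90% (simulation-based calibration). Fixed-truth coverage is only
  approximately nominal and fails by construction for truths deep in the
  prior tails, which is why calibration uses prior draws.
- `trend_scenario` builds a memoryless chain (all TPM rows equal within a
  season) whose state-4 share declines exactly linearly, giving a known
  expected trend (default −0.5 territories/season over 15 seasons at n = 10,
  share 0.85 → 0.15) against which `linear_trend` is checked. Detection
  intercepts are raised 1.5 logits over the defaults so imputation noise is
  small relative to the built-in signal.

## Numerical and design choices

- Julian dates are standardized by the pooled mean and sample SD (n−1),
  across blocks and years, and the center/scale are carried on `StudyData`
  so new dates can be placed on the same axis.
- All 16 transitions are estimable; none are fixed to zero. Rarely observed
  transitions (e.g. unoccupied → reproducing) are regularized by the
  hierarchy and will be prior-dominated in small datasets.
- Credible intervals are equal-tailed sample quantiles (90% → 5th/95th).
- Trend windows are inclusive at both ends; a year shared by two windows
  (e.g. 2002 in 1990–2002 and 2002–2014) belongs to both. Sub-window trends
  re-use the same fitted draws rather than refitting.
- `polynomial_trend` uses orthonormal polynomial contrasts (QR of the
  centered Vandermonde matrix, signs fixed positive); the degree-1 contrast
  equals the least-squares slope times ‖Yr − Ȳr‖.
- Posterior predictive p-values are Pr(T(rep) ≥ T(obs)) over retained draws;
  the statistic set (visit-level state frequencies, across-year SD of yearly
  detected-state counts, naive best-state counts per territory-year) covers
  visit, year, and territory aggregation. It is a generic reconstruction of
  replicate-and-compare checking for this model class, not a transcription
  of any specific published diagnostic.
- Degenerate inputs fail loudly: all-identical dates (no scale), empty data,
  single-season trends, states outside {1,2,3,4}, territories mapped to two
  blocks, duplicate visits (unless explicitly allowed).

## Verification problem sizes

The simulation studies are sized for a single CPU: calibration uses 20
replicates of 20 territories × 10 seasons with 2 chains × 4,000 iterations
(burn-in 1,000); trend recovery averages 6 replicates of 10 territories × 15
seasons; PPC calibration uses 10 replicates of 25 territories × 10 seasons
with 200 replicate datasets each. These sizes give stable pass/fail behaviour
while keeping the full battery to a few minutes.

## Known limitations

- Reduced-scale trend recovery shows mild attenuation (posterior mean ≈ −0.41
  for a built-in −0.5): the exchangeable-year hierarchy shrinks imputed
  yearly counts toward a common level, flattening trends when data are weak.
  The effect shrinks with more territories, visits, or iterations.
- The Metropolis blocks mix slowly for hyper-SDs of sparsely informed
  transitions; full-protocol chain lengths (or longer) are advisable for
  real datasets.
- Single-block fitting is serial; blocks are independent, so parallelism
  across blocks (or chains) is the obvious speedup, not implemented.
- No model-selection machinery (DIC/WAIC) and no covariates on transitions —
  both out of scope for this package.
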