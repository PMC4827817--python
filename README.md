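# msodyn — dynamic multistate occupancy models for territory monitoring

`msodyn` fits Bayesian dynamic **multistate occupancy models** to long-term
territory survey data, the kind collected in raptor monitoring programs such
as northern spotted owl (*Strix occidentalis caurina*) demography studies.
Each territory is in one of four latent states each breeding season —
1 = unoccupied, 2 = single owl, 3 = pair (non-reproducing), 4 = reproducing
pair — and repeated daytime visits yield an *observed* state that can
understate, but never overstate, the truth. The package is for quantitative
ecologists who need detection-corrected estimates of how many territories are
occupied or reproducing, and of long-term trends in those numbers.

## The model

Latent states evolve as a Markov chain: z_i1 ~ Categorical(φ₀), and

    Pr(z_t = n | z_{t−1} = m) = φ_t[m,n],

with each row of the 4×4 transition probability matrix (TPM) built from a
multi-logit link, baseline state 1:

    φ_t[m,n] = exp(β_{0,t}[m,n]) / (1 + Σ_{l=2..4} exp(β_{0,t}[m,l])),  n > 1.

Season effects are hierarchical, β_{0,t}[m,n] ~ N(μ[m,n], σ[m,n]²), so yearly
transition probabilities vary but borrow strength across years. Given the
true state m, each visit j produces an observed state from the detection
probability matrix (DPM), constrained by p[m,n] = 0 for n > m (a reproducing
pair can be recorded as anything 1–4; a single owl only as 1–2). The DPM rows
use the same multi-logit link with season-varying intercepts and linear +
quadratic standardized Julian-date terms, all with hierarchical normal
effects. Priors: Dirichlet(1,1,1,1) on φ₀, N(0, 2) on every hyper-mean,
Gamma(2, 0.5) on every hyper-SD. Every parameter is fitted separately per
survey block.

Inference is a blocked Gibbs sampler (numba-compiled): latent trajectories
are imputed exactly by forward-filtering backward-sampling, φ₀ is updated
conjugately, and the multi-logit effects and hyperparameters by adaptive
Metropolis-within-Gibbs. Because every draw imputes all z_it, population
summaries are posterior functionals: the number of territories in a state
set, N_t = #{i : z_it ∈ S}, and its linear trend

    T_L^(s) = Σ_t N_t^(s)(Yr_t − Ȳr) / Σ_t (Yr_t − Ȳr)²,

averaged over draws with equal-tailed 90% credible intervals from sample
quantiles. A T̃_L of −1.0 means an average loss of one territory in S per
year. Orthogonal-polynomial contrasts generalize this to quadratic trends,
and posterior predictive checks compare detected-state summaries between the
data and model replicates at the real survey design.

## Worked example

```python
import msodyn as mso

# synthetic 104-territory study: blocks A/B/C of 18/62/24 territories,
# seasons 1990–2014 (block C through 2006), median 3 visits per year
truth = mso.generate(mso.mendocino_preset(seed=1))
print(mso.summarize_design(truth.data).territories_per_block)

draws = mso.sample_posterior(
    truth.data,
    config=mso.McmcConfig(n_chains=2, n_iter=6000, n_burnin=1000, thin=10, seed=1),
    block="A",
)
trend = mso.linear_trend(mso.count_states(draws, {4}))
print(f"trend: {trend.posterior_mean:.2f} "
      f"(90% CRI {trend.cri_lower:.2f}, {trend.cri_upper:.2f})")
rep = mso.mean_transition_probs(draws, 4, 4)
print(f"P(reproduce | reproduced last year): {rep.posterior_mean:.2f} "
      f"(90% CRI {rep.cri_lower:.2f}, {rep.cri_upper:.2f})")
```

which prints

```
{'A': 18, 'B': 62, 'C': 24}
trend: -0.21 (90% CRI -0.25, -0.18)
P(reproduce | reproduced last year): 0.69 (90% CRI 0.52, 0.83)
```

The trend says block A lost on average about a fifth of a reproducing
territory per year in this synthetic realization; the transition summary is
the probability, in an average year (hyper-means pushed through the
multi-logit link), that a territory that reproduced last season reproduces
again. Real data enter through `mso.read_survey_table` (long CSV with header
`block,territory,year,julian_date,observed_state`, or XLSX with a column
map), followed by `mso.standardize_dates` before fitting.

The same workflow is scriptable from the shell:

```sh
msodyn simulate --preset mendocino --seed 1 -o out/
msodyn fit out/survey.csv --block A --chains 2 --iters 6000 --burnin 1000 --thin 10 -o out/fit/
msodyn summarize out/fit/draws_A.npz --windows 1990-2002,2002-2014,1990-2014 -o out/summ/
msodyn ppc out/survey.csv out/fit/draws_A.npz -o out/ppc/
```

The default `fit` settings are the full protocol (3 chains × 55,000
iterations, burn-in 5,000, thinning 1/100); the reduced settings above are
appropriate for small synthetic datasets.

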