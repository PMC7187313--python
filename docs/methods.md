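# Methods

`lynxcast` implements a Bayesian age-structured state-space model for a
harvested Eurasian lynx population monitored through annual counts of
*family groups* (an adult female with dependent young, verified by
snow-tracking), together with predictive-process forecasting under
harvest scenarios and a regression model of the managers' quota-setting
behaviour. This note records the model, the estimation machinery, the
synthetic-data conditions, and the design choices that were genuinely
open.

## Population model

**States.** The model tracks females only, in three stages at the
pre-breeding February census: kittens (9 months), subadults (21 months)
and adults (33+ months). Latent states `n[i, j, t]` are continuous
positive reals (required by the lognormal process model) for management
region `j`, grouped into three geographical areas `k` (1 northern
Sweden, 2 southern Norway, 3 northern Norway) that share demographic
rates.

**Projection.** Births pulse in June; harvest pulses in March,
immediately after the census, so the recorded harvest vector `h` is
subtracted *before* projection:

    mu[t] = A_k (n[t-1] - h[t-1])

with the pre-breeding projection matrix

    A_k = [ 0                      r1 (phi2^1/4 - rho phi2^1/8)   r2 (phi2^1/4 - rho phi2^1/8) ]
          [ phi1 - rho phi1^1/2    0                              0                            ]
          [ 0                      phi2 - rho phi2^1/2            phi2 - rho phi2^1/2          ]

`phi1`, `phi2` are telemetry-based annual survival probabilities
excluding harvest; `r1`, `r2` are female kittens recruited per 2-yr-old
and per 3+-yr-old female; `rho` is an area-level *additional mortality*
(mostly poaching and other deaths unseen by telemetry) acting at
mid-interval, hence the `phi^1/2` (full year) and `phi^1/8`
(census-to-birth quarter) factors. The fecundity parenthesization
applies `rho` to the mother's survival-to-breeding *before* multiplying
by recruitment; this reading reproduces the published posterior-median
growth rates (1.01 and 1.19 from the posterior-median vital rates),
whereas the alternative reading gives 0.95 for area 1 and is rejected
on that ground. The potential growth rate `lambda_k` is the dominant
eigenvalue of `A_k` (harvest excluded, `rho` included).

**Stochastic layers.**

* Process: `log n[t] ~ Normal(log mu[t], sigma_p^2 I)` — one process
  standard deviation shared by all areas, covariance diagonal.
* Observation: `y[j, t] ~ Poisson(f[k, t] * sum_i n[i, j, t])`, where the
  family-groups-per-female ratio `f[k, t]` is a yearly beta random effect
  with area-level mean `F_k` and sd `sigma_F_k` (moment-matched beta
  shapes).
* Initial condition: the first-census female total `y1 / f[k, 1]` is
  split across stages by `psi ~ Dirichlet(3.15, 2.48, 9.16)`.

**Priors** (informative ones from long-term telemetry studies):
`phi1 ~ beta(9.1, 1.01)`, `phi2 ~ beta(20.5, 0.74)`;
`r1 ~ beta(4, 14)` and `r2 ~ beta(55, 85)` in areas 1 and 3,
`beta(9, 9)` and `beta(53, 53)` in area 2; `F_k ~ beta(126, 278)`;
`sigma_F_k ~ beta(20.7, 877)`; vague `rho_k ~ uniform(0, 1)` and
`sigma_p ~ uniform(0, 4)`. Note one published inconsistency: the
`beta(4, 14)` row is quoted with mean 0.19 although the shapes imply
4/18 = 0.222; the shapes are taken as authoritative here. Similarly
`beta(9, 9)` implies sd 0.115 (quoted 0.12) and `beta(20.5, 0.74)`
implies mean 0.965 (quoted 0.96) — two-significant-figure roundings.

**Support constraints.** Parameter combinations for which any matrix
entry would go negative (`rho > sqrt(phi)`-type violations) are outside
the support. Over-harvest of a latent state (recorded removals
exceeding the state) floors the post-harvest state at 1e-6 with a
logged warning; the observation rate is floored at 1e-10.

## Estimation

The joint posterior over `(phi, r, F, sigma_F, rho, sigma_p, psi, f, n)`
is sampled by a hand-written adaptive Metropolis-within-Gibbs scheme
(numpy/scipy only). The update cycle per iteration:

1. **Latent states** — region-years of equal year-parity are
   conditionally independent given their neighbours, so a checkerboard
   sweep updates all same-parity region-years at once, proposing the
   three stages jointly (parity alternates between iterations).
2. **Detection ratios `f`** — conditionally independent across
   area-years; one vectorized parallel sweep. First-census ratios feed
   the derived initial states and get individual updates.
3. **Area scale moves** — a joint proposal multiplies all of an area's
   states by `exp(eps)` while dividing its `f` values and `F_k` by the
   same factor. Observation rates are exactly invariant, so the move
   walks the abundance-versus-detection ridge that single-site updates
   cross only slowly; the acceptance ratio carries the Jacobian factor
   for the rescaled coordinates.
4. **Demographic scalars** — sequential random walks against cheap
   partial likelihoods (process terms for rates entering the matrix,
   hierarchy terms for `F`, `sigma_F`), mixed with *adaptive
   independence proposals*: beta distributions moment-matched (variance
   doubled) to running burn-in estimates of each posterior, frozen when
   burn-in ends.
5. **Non-centered moves** for `phi1`, `phi2`, `sigma_p` and `psi` —
   these parameters are pinned by the latent trajectory (their full
   conditionals are far narrower than their marginals). Holding the
   standardized process residuals fixed and rebuilding the trajectory
   forward turns the acceptance ratio into an observation-likelihood
   ratio, restoring marginal-rate mixing. This is the
   centered/non-centered interweaving strategy familiar from
   state-space samplers.

Proposal scales adapt by Robbins-Monro toward 44% acceptance (30% for
blocks) during burn-in only; all adaptation freezes at the end of
burn-in, so the retained chain is a valid Markov chain. Every chain is
driven by one `numpy` Generator seeded from `(seed, chain)`: identical
seed, settings and data give bit-identical chains.

Production settings are 3 chains x 100,000 iterations after a 50,000
burn-in. Tests and the analysis scripts use reduced settings (thousands
of iterations); the parameter-recovery experiment shows those suffice
for calibrated `rho` and `sigma_p` intervals at the study's data size.
Sampler correctness is verified by (a) a conjugate reduction — with
states and all other parameters frozen, the `sigma_p` conditional has a
closed form that a plain Metropolis chain over the model's joint
density must reproduce (Kolmogorov-Smirnov check) — and (b) a
term-by-term oracle test of the joint density against independent
`scipy.stats` evaluations on a one-region, two-year example.

## Evaluation suite

* **Convergence**: Brooks-Gelman potential scale reduction factors with
  sampling-variability degrees-of-freedom correction and an F-quantile
  97.5% upper limit (the estimator classic MCMC toolboxes report).
  The workflow's pass criterion is every upper limit below 1.11. The
  initial stage composition `psi` is the slowest-mixing quantity at the
  full 11-region scale (its posterior is nearly as broad as its
  Dirichlet prior while its full conditional is narrow); production-
  length chains are required for its upper limit to clear the bar,
  which is why the desk-scale convergence demonstration uses a
  3-region dataset.
* **Posterior predictive checks**: Bayesian P values with a
  Freeman-Tukey discrepancy `sum (sqrt(y) - sqrt(rate))^2` per region
  plus a dataset-level total. The discrepancy is swappable; published P
  values based on an unnamed statistic are treated as soft references
  only.
* **Residual ACF**: autocorrelation (statsmodels) of
  `y - posterior mean of (f * sum n)` per region; lag 0 is exactly 1.
* **Sensitivity**: refits with one informative prior at a time swapped
  for uniform(0, 1), the `sigma_F` prior mean inflated by a factor
  (default 1.3), and first-census counts scaled by +/-30%.

The simulation-based calibration experiments in the test suite use the
following problem sizes, chosen so each experiment isolates what it
measures: credible-interval coverage of `(rho_k, sigma_p)` runs 20
replicate fits at the full study scale (11 regions x 20 years, one
chain of 6,000 iterations after 3,000 burn-in); Bayesian-P calibration
runs 50 replicates on compact 3-region, 10-year datasets (one chain,
2,000 iterations); the convergence demonstration runs three chains of
20,000 iterations on a 3-region, 15-year dataset.

## Forecasting

Forecasts are predictive-process distributions: every retained draw of
`(theta, n_T)` is propagated forward — subtract the harvest pulse,
project with that draw's matrices, add lognormal process noise — and
converted to observable family groups with a *fresh* `f` drawn from the
fitted hierarchy plus Poisson sampling, i.e. the full posterior
predictive of the count. The step leaving the final data census uses
the recorded harvest that already followed it; scenario quotas apply to
later, forecasted censuses (matching the management timeline in which a
quota decided this winter acts after next February's census).

Scenario quotas are allocated to sex/age classes by a multinomial draw
at the observed bag composition (0.57 male / 0.34 female 21+ months /
0.09 female kitten); males leave the female-only state untouched, and
older females are split subadult-versus-adult by a Dirichlet-weighted
draw at the current draw's stage composition (concentrations equal to
the stage counts). Quota filling defaults to 100%; the observed filling
fractions (about 0.80 Sweden, 0.77 Norway) are a scenario switch.

Goal probabilities are empirical proportions of draws below / within /
above the objective. Boundary convention: "below" is strictly less than
the lower bound, "above" strictly greater than the upper; ties count as
within. A single-value objective has no "within" zone (reported as NaN)
and ties count as meeting the objective.

## Quota decision model

Set quotas are regressed on the previous census:
`q_t ~ Poisson(H_t)`, `log H_t ~ Normal(log(max(eps, b0 + b1 x_{t-1})),
sigma_q^2)` with `eps = 1e-6`. Model 1 (strict proportional strategy)
omits `b0`; model 2 (threshold strategy) includes it, and the census
threshold below which the predicted quota collapses to zero is
`-b0 / b1` (meaningful for `b0 < 0`; draws with `b0 >= 0` count toward
`P(threshold <= 0)`). The published mean form wraps `max(0, .)` around
a log whose argument can be nonpositive; flooring the *argument* keeps
the density proper while preserving the intended zero-quota regime —
the literal reading would force a median quota of at least one animal
everywhere, contradicting the threshold concept.

Priors: `b ~ Normal(0, sd 3000)`, `sigma_q ~ uniform(0, 4)`. The
source notation "normal(0, 3,000)" is ambiguous (a BUGS-style precision
of 3,000 would be strongly informative, the opposite of the stated
intent); the vague sd reading is used.

Fitting augments one latent `log H_t` per pair (vectorized parallel
updates; they are conditionally independent given the coefficients),
with adaptive random walks on `(b0, b1, sigma_q)` plus a correlated
intercept/slope move that holds the prediction at the mean census
fixed. Latents for zero-quota pairs initialize at the regression
location (near `log eps`), not at `log 0.5` — starting them at the
observed scale traps `sigma_q` in a high-noise local mode. A
Gauss-Hermite marginal likelihood (latents integrated out) serves as
the independent cross-check; in the `sigma_q -> 0` limit it reduces to
the plain Poisson regression likelihood.

The threshold is identified only up to the gap between the largest
zero-quota census and the smallest positive-quota census; recovery
tests place the generating threshold in the interior of that gap.

## Synthetic data

The generator runs the model forward under the study conditions:
3 areas split into 4 + 4 + 3 management regions, 20 census winters,
vital rates at the informative-prior means, additional mortality
(0.18, 0.09, 0.06) per area, `sigma_p = 0.25`, `F = 0.312`,
`sigma_F = 0.023`, and initial counts of (20, 10, 10) family groups per
region per area. Harvest follows area-specific threshold quota rules
scaled to region level — a weak-slope/high-threshold rule for area 1
and steeper, lower-threshold rules (slope 1.6) for the faster-growing
areas 2 and 3 — chosen so that simulated area counts equilibrate in the
tens of family groups, the magnitude of the real monitoring series.
Quotas are decided with a one-year lag (the quota acting after census
`t` is based on census `t-1`), filled stochastically, split by the
observed bag composition, and capped by the animals present; realized
removals are integers via binomial/multinomial draws. A region whose
stages all drop below one animal is truncated (later counts marked
missing) with a logged note, so over-harvest stress tests run without
raising.

What the generator does *not* emulate: density dependence, dispersal
between regions, observer effort trends, spatial correlation of process
noise, and cross-year correlation in detection. Passing recovery and
calibration tests therefore demonstrates internal consistency of model
and sampler under the model's own assumptions — not robustness of the
published inferences to violations of those assumptions in field data.

## Data layout

One CSV dialect everywhere: UTF-8, comma-delimited, header
`country, region, area, year, family_groups, harvest_female_kitten,
harvest_female_older, harvest_male, quota`, one row per region-year,
blank cells for missing censuses or unset quotas. Because harvest data
distinguish female kittens from older females but not subadults from
adults, older-female removals are split between those stages on read at
the stable-age ratio of the area's prior-mean matrix; a write/read
cycle preserves counts, quotas, kitten harvest, and the older-female
total exactly. Posterior chains export as one CSV per chain plus a JSON
metadata file recording seed, settings, and convergence flags.

## Known limitations

* Single-site mixing of `psi` and the survival parameters at the full
  11-region scale is slow even with the non-centered moves; the
  convergence flag is honest about it, and production-length runs are
  the documented remedy.
* The latent-state floor (1e-6) makes the posterior technically
  discontinuous at over-harvest boundaries; with the study's data this
  region has negligible mass.
* `f` is independent across areas and years given its hierarchy; any
  synchrony in detection conditions (snow quality) is not modelled.
* The quota regressions condition on the census index, not on the
  latent abundance, mirroring how the decisions were actually made.
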