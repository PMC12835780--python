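# Methods

## Model and objectives

`fairsurv` fits proportional-hazards models with a neural log-hazard:
h(t | x) = h₀(t) · exp f_θ(x), where f_θ is a multilayer perceptron
(input layer p→32, four hidden 32→32 layers, SELU activations, scalar
output; no batch normalization or dropout). The sensitive attribute s ∈
{1..K} is never an input to f_θ; it enters only through the training
objectives and the evaluation metrics.

Three objectives share one partial-likelihood core (Breslow convention for
tied event times — all dⱼ events at tⱼ share the risk set R(tⱼ) = {l : o_l ≥
tⱼ}):

* **baseline** — negative mean partial log-likelihood over observed events.
* **fair** — baseline + λ·Σ_k (f̄_k − f̄)², the squared deviation of each
  group's mean predicted log-hazard from the overall mean. λ defaults to 1
  (the penalty enters the loss with unit weight); groups absent from a
  mini-batch contribute nothing for that step.
* **groupdro** — max over k ∈ {0, 1, …, K} of the group-restricted loss:
  the numerator sums over group-k events only and is normalized by that
  group's event count, while risk sets are always built over the entire
  set being evaluated. k = 0 is the unrestricted loss, kept inside the max
  so optimizing the worst group can never fully sacrifice the global fit.
  A group with no events in the evaluation set cannot form its term and is
  skipped (logged).

All three objectives are invariant to adding a constant to every score, a
property the tests assert directly.

### Optimization

SGD with momentum 0.9, initial learning rate 0.01, step decay ×0.1 every 5
epochs, weight decay 0.001 on all parameters, batch size 128, at most 100
epochs, early stopping with patience 5 on the validation objective, best
parameters restored. Weights are initialized uniformly on ±1/√fan_in from
the run seed. The network and backpropagation are implemented directly in
numpy; the loss gradients with respect to the scores have closed forms and
are chain-ruled through the MLP by hand. Training is deterministic given
the seed (single-threaded numpy arithmetic).

**Risk sets under mini-batching.** The partial likelihood defines risk sets
over the whole cohort, which is incompatible with naive mini-batching.
During stochastic training the risk sets are formed *within each batch*
(batches internally sorted by time) — standard deep-Cox practice; every
reported or monitored loss (per-epoch train/validation objectives,
anything user-facing) uses full risk sets within its cohort. Batches with
zero events are skipped and counted, never fatal.

**GroupDRO step rule.** The worst-case objective is optimized with a
per-batch hard max: the gradient flows through the single worst group's
term each step (k = 0 included in the max). An exponentiated-gradient soft
weighting over group terms is available behind `dro_soft_weighting` but is
off by default. Group-stratified batch sampling is likewise available
behind a flag (default off).

**Early-stopping monitor.** "Validation loss" is the model's own training
objective evaluated on the validation split with full within-split risk
sets — so the fair model early-stops on penalized loss and the groupdro
model on its worst-case loss.

## Preprocessing

CSV cohorts are read with named time/event/group columns; every other
column is a covariate. Categorical covariates are one-hot encoded and
missing values become a distinct `missing` indicator level (no imputation);
continuous covariates must be complete and numeric. Continuous columns are
z-scored with training-split statistics only, applied unchanged to
validation/test data (prevents leakage; the means/SDs are logged and stored
with the model). Time units are the caller's responsibility and are never
rescaled. Splits are stratified on event status: within each event stratum
subjects are shuffled by the split seed and cut at round(fraction·n), so
both partitions' event rates match the cohort's up to rounding.

## Baseline hazard and survival curves

After training, the Breslow estimator converts scores to absolute risk:
h₀(tⱼ) = dⱼ / Σ_{l∈R(tⱼ)} exp f(x_l) at each unique event time, with
subjects censored exactly at tⱼ kept in R(tⱼ) (the standard boundary
convention). Survival is the right-continuous step function
Sᵢ(t) = exp(−H₀(t)·exp f(xᵢ)). With constant scores the increments reduce
exactly to Nelson–Aalen dⱼ/|R(tⱼ)|, and a constant score shift c rescales
increments by e^{−c} and the subject multiplier by e^{c}, leaving Sᵢ(t)
unchanged — both asserted numerically.

## Evaluation metrics

Comparable pairs are (i, j) with oᵢ < oⱼ and δᵢ = 1. Three pair sets per
group k: all pairs (Harrell's C), within-group (both members in k), and
cross-group (exactly one member in k). Each cross pair belongs to exactly
two groups' cross sets, giving the bookkeeping identity |all| = Σ|within| +
½Σ|cross|, asserted on random cohorts. Concordance counts score ties at ½.
Counting uses a Fenwick-tree pass over time-sorted subjects (one tree per
group, numba-compiled), checked exactly against an O(n²) enumeration
oracle. An empty pair set (e.g. a group with no events) yields an explicit
defined-missing value, never NaN.

**IPCW Brier score.** BS(t) = (1/n_k) Σ_i w_i(t)(1(o_i > t) − S_i(t))² with
w_i(t) = δᵢ·1(oᵢ≤t)/Ĝ(oᵢ⁻) + 1(oᵢ>t)/Ĝ(t); Ĝ is a Kaplan–Meier fit of the
censoring distribution on the *full* cohort (left-limit convention at event
times). Terms whose required Ĝ value is zero are dropped and counted. The
integral over (0, τ] uses the trapezoid rule on the unique event times up
to τ (thinned to ≤100 quantile points for large cohorts — a numerical grid
resolution choice, exact on small instances) and is divided by τ.

**Integrated calibration index.** At each grid time (event-time deciles up
to τ, plus 0 and τ) a calibration curve is fit: a weighted local-linear
(tricube, span 0.75) smoother of the IPCW-weighted alive indicator on the
predicted survival probability, clipped to [0,1]. For cohorts above 512
subjects the smoother operates on weighted quantile bins of the
predictions (bounding cost; fitted values interpolate between bins). ICI
is the group-mean |predicted − calibrated| averaged over the grid
(trapezoid / τ). Smoothing is per time point; degenerate (constant)
predictions fall back to the IPCW-weighted empirical survival, logged.

**Horizon.** τ defaults to the 99th percentile of follow-up times, avoiding
the unstable tail of the censoring weights; configurable.

**Bootstrap.** Percentile 95% CIs from subject-level resampling (default
B=1000 where CIs are requested); replicates where a metric is undefined
(e.g. the group vanished from the resample) are skipped and counted, with a
warning above 10% skips.

## Risk-stratified audit

Subjects are binned by predicted-score quantiles: low (below the q_low
quantile), high (above q_high), mid otherwise; defaults (0.25, 0.75). The
strict-inequality rule means boundary ties fall to mid, and fully
degenerate (all-equal) scores place everyone mid with a warning. The
alternative boundary scheme (mid 25–50%, low bottom 50%) is available by
passing cutpoints (0.50, 0.75); neither is privileged. Within each stratum,
per-group Kaplan–Meier curves are estimated and all group pairs compared
with two-sided log-rank tests (lifelines); p-values are reported raw by
default with an optional Bonferroni flag (over the pairs within a stratum).
A fair model should show no systematic survival differences between groups
inside one predicted-risk stratum; a group whose observed survival sits
significantly below the others in the high-risk stratum is having its risk
underestimated.

## Synthetic cohorts

The generator emulates the statistical structure of a large clinical
registry cohort. Subject i in group g gets latent event time
T = scale_g · (−log U / exp η)^(1/shape_g) — Weibull proportional hazards by
inverse transform — with η = xᵀβ + γ_g (+ withheld heterogeneity, below),
censoring C = min(Exponential(rate), admin horizon), observed time
min(T, C), event 1(T ≤ C). Latent times and censoring come from two
independent streams spawned from the seed, so changing the censoring
configuration never changes latent outcomes.

The registry-like default (`default_ncdb_like`):

* n = 20,000; five groups with probabilities renormalized from the printed
  78.5 / 13.2 / 4.5 / 1.9 / 2.0 % mix (they sum to 100.1%; stored
  renormalized).
* Weibull shape 1.1, scale 10 (time in years); exponential censoring rate
  0.04/year with a 15-year administrative horizon (≈37% censored —
  realistic heavy but not dominant censoring).
* Ten standard-normal covariates; β = (0.5, −0.5, 0.3, −0.3, 0.2, 0, 0, 0,
  0, 0).
* Group log hazard ratios γ = (0, +0.5, −0.2, −0.2, −0.2): the second group
  has markedly lower survival, the small groups slightly better, matching
  the qualitative ordering of observed registry survival curves.
* Proxy structure: the two zero-coefficient covariates have group-shifted
  means (x9: +0.8 for group 2, −0.3 for groups 3–5; x10: +0.5 for group
  2). The group effect on the *hazard* enters only through γ — the label is
  never a covariate — but real registries carry socioeconomic/clinical
  proxies that partially identify group, and without any proxy a
  group-blind model could not react to group structure at all.
* Withheld heterogeneity: group 2 additionally receives a per-subject
  N(0, 0.6²) log-hazard term drawn outside the covariate matrix. Part of
  that group's risk is therefore unexplainable by any model, which is what
  makes a model trained on the average loss under-serve it — its
  cross-group C sits below the majority group's in essentially every
  simulation.

What the generator does **not** emulate: the detailed covariate marginals
of a real registry (mixed categorical batteries, year effects), informative
(covariate-dependent) censoring, and calendar-time structure. Passing tests
on these cohorts show the estimators and objectives behave as designed
under a controlled proportional-hazards world; they do not certify
performance on real registry data.

## Directional fairness benchmark

The headline property check trains all three objectives on ten seeded
registry-like cohorts (seeds 0–9, n = 20,000 each) and compares the
max−min spread of cross-group C across the five groups, evaluated on the
full cohort (the spread on a 20% validation split is noise-dominated for
groups of ~80 subjects; full-cohort evaluation mirrors reporting metrics at
full-cohort sample sizes). On these runs the baseline's cross-group C for
group 2 falls below group 1's in 10/10 seeds, and the worst-case (groupdro)
objective narrows the gap relative to baseline in 8/10 seeds. The
mean-parity (fair) objective does **not** reliably narrow it here (4/10):
pulling group mean log-hazards together suppresses exactly the
proxy-driven score elevation that earns group 2 its cross-group
concordance, so under this generative structure the penalty trades overall
discrimination without closing the spread. Empirical gains reported for
mean-parity penalties on real registry data plausibly come from baseline
over-separation structure (proxies entangled with genuine risk factors)
that this controlled generator deliberately does not contain. The test
suite asserts the expected direction for both objectives; the fair one is
expected to fail on these study conditions and is left failing rather than
re-tuning the generator around it.

## Problem sizes and numerical choices

Simulation-based tests use the sizes stated above (10,000–50,000 subjects
for recovery/tracking oracles; 20,000 for the directional benchmark;
1,000 replicates for log-rank calibration), chosen to make sampling error
small relative to the asserted effects. Log-sum-exp terms are max-shifted;
the concordance kernel rank-compresses scores; percentile CIs use the
2.5/97.5 points; quantile-based grids are deduplicated before trapezoid
integration. Degenerate inputs (no events in a subset, empty pair sets,
all-equal scores, groups missing from a resample) produce explicit errors,
defined-missing values, or logged fallbacks as documented above — never
silent NaNs.

## Known limitations

* Proportional hazards is assumed throughout (generation, fitting,
  Breslow); no test probes misspecified hazards.
* The Breslow (not Efron) tie convention is used end-to-end.
* ICI smooths per time point; pooling over time is a plausible alternative
  reading and would give slightly different values.
* GroupDRO's per-batch hard max is noisy for very small groups (a 2% group
  contributes ~2–3 subjects per 128-batch); the soft-weighting flag
  mitigates but is off by default.
* The fairness benchmark is directional, not a calibration of real-world
  effect sizes.
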