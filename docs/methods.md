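# Methods

`armabehave` estimates short-term latent behavioral states of a nocturnal,
fossorial mammal (the motivating system is GPS + accelerometer biologging
of giant armadillos in the Brazilian Pantanal) and relates those states to
land cover. This note records the models, the parameter choices, and the
reasoning behind design decisions that were genuinely open.

## Data model and preprocessing

Raw inputs are a GPS fix table (nominal 7-min schedule, projected metric
coordinates, satellite counts) and an accelerometer table whose "activity
count" is the number of one-second epochs with any above-zero acceleration
within a 5-min window (0–300). The filtering cascade removes (in order):

1. fixes with ≤ 4 satellites (aberrant positions);
2. zero activity counts (animal in its burrow — the analysis concerns
   aboveground behavior only);
3. steps longer than 800 m per ~7-min interval (biologically implausible)
   and steps whose duration falls outside 7 ± 1 min;
4. movement observations with no accelerometer record within 60 s.

Movement metrics are computed per *burst* — a maximal run of consecutive
retained steps — so no step length, speed or turning angle ever spans a
gap. Speed is step length divided by the actual step duration. The turning
angle is the signed heading change between consecutive steps, wrapped to
(−π, π], counter-clockwise positive; the first step of a burst has no
turning angle and the observation is retained with that stream missing
(the mixture model supports stream-wise missingness), which discards less
data than dropping rows.

Stream matching is greedy nearest-first: candidate (observation, record)
pairs within 60 s are taken in increasing |Δt|, each record used at most
once. On a 7-min/5-min pair of grids anchored at the same origin, GPS
offsets modulo 300 s cycle through {0, 120, 240, 60, 180}, so roughly
three in five observations find a record within 60 s; this structural
loss is a property of the instrument schedules, not of data quality.

Discretization uses fixed, data-independent edges so results are
comparable across datasets: activity counts in 6 equal bins on (0, 300];
speed in 6 equal bins on (0, 1] m/s plus an overflow bin above 1 m/s
(well under 1% of observations in the motivating data exceed 1 m/s);
turning angle in 10 equal bins on (−π, π] with edges −π + k·π/5. All
intervals are right-closed with the left edge of bin 1 closed, so each
metric's minimum falls in bin 1 and its printed maximum (300 counts,
1 m/s, π rad) falls in the top regular bin. Under this convention a
turning angle of exactly 0 lies in bin 5 = (−π/5, 0].

## Latent-state mixture model

Observations are treated as exchangeable draws from a finite mixture with
truncation `K_max` (default 10). Each state has one categorical
distribution per data stream; the observation likelihood is the product
over present streams. Mixing weights follow a truncated stick-breaking
construction, v_k ~ Beta(1, α), π_k = v_k ∏_{j<k}(1 − v_j), v_K = 1, with
α = 0.1: small α concentrates prior mass on few effective states, so the
number of supported states is estimated rather than fixed. The
state-dependent categoricals carry symmetric Dirichlet(φ₀) priors.

Inference is Gibbs sampling over assignments z, categoricals φ, and
sticks v. The recorded trace is the marginal log-likelihood
Σᵢ log Σₖ πₖ ∏_d φ_{k,d}[binᵢ_d]; an advisory Geweke-style z-score on the
trace is computed (ESS-adjusted via arviz), but convergence judgment
follows the trace itself, as is conventional for this model family.
Default run length is 20,000 iterations with the first 10,000 as burn-in
and no thinning.

Two implementation choices depart from the most naive sampler, both made
after the naive versions demonstrably failed on simulated data:

* **Dirichlet concentration φ₀ = 1 (flat), not sparse.** With φ₀ ≈ 0.1 the
  posterior rewards carving any high-entropy stream (e.g., a near-uniform
  turning-angle distribution) into complementary peaked pseudo-states:
  assigning each observation to the half-component that favors its bin
  gains up to log 2 per observation, which overwhelms the stick-breaking
  penalty at realistic sample sizes. A flat Dirichlet removes the reward
  for spurious peakedness while leaving genuine multi-bin structure
  identifiable. φ₀ remains exposed in `MixtureConfig`.
* **Over-segmented initialization.** The truncated-stick Gibbs sampler
  merges redundant states readily (assignments drift to the richer
  duplicate) but almost never splits an established state, because vacant
  components carry negligible stick weight and cannot nucleate. Default
  initialization therefore runs k-means (on standardized ordinal bin
  features, with the turning-angle bin folded about zero so reversal-heavy
  and directed movement separate) at k = K_max and lets the sampler merge
  downward. Uniform random initialization remains available
  (`init="uniform"`) and is used for the exactness checks on tiny
  instances, where mixing is complete either way.

**State selection** ranks states by their mean share of observations
across retained iterations and keeps the minimal prefix reaching 90%
cumulative share. **Assignment** labels an observation with its
maximum-membership retained state only when that membership is ≥ 0.75
(inclusive); otherwise "unclassified". Membership is the fraction of
retained iterations assigning the observation to the state — the
fraction-of-assignments reading of "average probability", with the
threshold applied per observation. **Naming** orders retained states by
the posterior-mean expected speed bin (ties broken by mean activity bin);
a four-state solution receives the canonical labels vigilance-excavation
(VE), local search, exploratory, transit, slowest first.

### Identifiability of single-stream differences

A property of mixtures of product-categoricals worth recording: two
components that differ in exactly **one** stream are unidentifiable,
because replacing them with a single component whose categorical is their
weighted average reproduces the mixture likelihood exactly (the shared
streams factor out). Separability therefore requires cross-stream
correlation: a pair of states differing in two or more streams is
identifiable; a pair differing in one stream will be merged by the
sparsity prior regardless of how far apart the two distributions are.
This is the mechanism behind the accelerometer-ablation experiment below,
and the reason the merged pair cannot be rescued by longer chains.

A second, subtler property shapes the recovery experiments: for two
*overlapping* components, the posterior places genuine mass on boundary
observations belonging to either state, and the feedback between leaked
assignments and the adapted categorical is near-critical (the summed
likelihood ratios over one component telescope to its size). Posterior-
mean categoricals therefore blend slightly at class boundaries, with an
upper bound set by the mass the donor state carries inside the receiving
state's support. The default synthetic preset keeps that bound small by
giving the vigilance-excavation state an essentially pure ±π turning
signature and local search only ~3% of its turning mass in those bins.

## Activity budgets

Budgets pool all individuals. Hourly transmission counts include
unclassified observations; state proportions are computed among
classified observations only, per hour of day in a configured local zone
(default `Etc/GMT+4`, i.e., UTC−4, the study region's offset). Hours with
no classified observation report missing proportions, not zeros. Overall
proportions are formed with exact rational arithmetic on counts and sum
to one identically.

## Habitat covariates and regression

Land-cover rasters (four classes: forest, closed savanna, open savanna,
floodable grassland; one raster per season) are stored as plain-text ESRI
ASCII grids in the track CRS; seasons are dry = April–September,
wet = October–March, selected by calendar month. Covariates are the class
proportions among raster cells whose centers lie within 30 m of the fix
(cell-center-in-circle rule: deterministic and bit-for-bit reproducible;
area-weighted intersection would differ negligibly at 30 m cells).
Observations whose buffer misses the raster are flagged, excluded, and
counted.

The regression is a Bayesian multinomial (categorical-logit) mixed model:
reference state VE, baseline class closed savanna (omitted), fixed
effects linear + quadratic in the three remaining class proportions
(uncentered, since the marginal-effect axis is the raw proportion), a
per-individual random intercept per non-reference state with independent
scales σ_k (the minimal reading of a random effect on the intercept), and
regularizing priors Normal(0, 1.5) on all fixed effects and
half-Normal(0, 1) on σ_k — checked by prior predictive simulation to keep
state probabilities away from degenerate corners. Unclassified
observations are excluded, mirroring the budgets' omission rule.

Sampling is Hamiltonian Monte Carlo written in-package (numba-compiled
gradients; non-centered random effects; dual-averaging step-size
adaptation to 0.8 acceptance; diagonal mass matrix estimated from the
first warmup half; jittered 8–32 leapfrog steps), run as independent
chains (default 4 × 1000 warmup + 1000 draws). Rank-normalized R-hat and
bulk ESS are computed per fixed effect and σ_k via arviz; R-hat > 1.01
raises a named warning. The sampler is validated three ways: against
maximum likelihood (statsmodels MNLogit) on a well-identified linear-only
design, by simulation-based calibration (95% intervals cover a fixed
truth at nominal rate over replicate datasets), and by determinism under
a fixed seed.

A caution on interpretation: quadratic logit coefficients of proportions
on [0, 1] are intrinsically weakly identified (x and x² correlate at
~0.97), so individual posterior means shrink noticeably toward the prior
at realistic sample sizes even though predicted probabilities and
marginal-effect curves are well determined. Calibration experiments
should therefore assess ensemble error and interval coverage, not
per-coefficient point error.

Marginal-effect curves set the focal class to p, closed savanna to 1 − p,
the other classes to 0, and random intercepts to 0 (population level),
reporting pointwise posterior means with 50% and 95% bands.

## Synthetic data generator

The generator stands in for field data and defines the conditions all
recovery experiments run under: 7 individuals, one nocturnal bout per
night (mean ≈ 5 h, truncated normal), 35 nights each, GPS every 420 s
with small whole-second clock jitter, accelerometer on an exact 300 s
grid extending an hour past the bout on both sides (burrow time emits
zero counts). At each step a latent state is drawn — i.i.d. from fixed
weights by default, matching the mixture model's exchangeability
assumption, or from a multinomial logit in local buffered habitat with
known coefficients; a Markov persistence knob exists for robustness
experiments only. Heading evolves by the state's von Mises turning draw;
displacement is speed × actual step duration, so measured speed equals
the drawn speed exactly. Activity counts are Binomial(300, p_state) with
p taken from the state active at the record's window midpoint — for every
observation that survives stream matching, that midpoint provably lies
inside the observation's own step, so matched counts always reflect the
observation's state. Artifacts are injected at configurable rates with
ground-truth flags: low-satellite fixes (n_sat ≤ 4), zeroed activity
counts, and teleported positions whose offsets guarantee a > 800 m step.

Default state weights are (0.18, 0.40, 0.30, 0.12) in the order VE,
local search, exploratory, transit — the diel-budget ranking of the
motivating system (local search and exploratory dominate, transit
rarest), with every weight above the ~10% floor the 90% cumulative-share
selection rule needs to retain a fourth state. Emission defaults
(speed gamma means 0.03/0.06/0.30/0.75 m/s; turning von Mises
concentrations 10/1.2/3/6 centered at π for VE and 0 otherwise; activity
success probabilities 0.10/0.28/0.55/0.85) reproduce the qualitative
state portraits — slow high-turn low-activity VE, slow flat-turn local
search, faster directed exploratory, fast highly-directed high-activity
transit — while keeping between-state boundary mass small enough for
posterior-mean parameter recovery (see the near-criticality note above).

The ablation preset separates transit from exploratory by activity
(disjoint bins) plus a speed shift, with identical turning distributions.
With all three streams the activity–speed correlation identifies the
pair; with speed + turning only the difference is single-stream, hence
exactly unidentifiable, and the sparsity prior merges them — the
accelerometer is what makes the fast-state distinction possible.

What the generator does **not** emulate: GPS positional error (beyond
planted teleports), satellite-geometry structure in fix quality, raw
tri-axial waveforms (only summarized counts), home-range memory or
burrow-return behavior, and within-bout temporal autocorrelation of
states under the default i.i.d. process. Passing recovery tests on this
generator therefore demonstrates correctness of the estimation machinery
under the model's own assumptions, not robustness to the autocorrelation
and measurement pathologies of real tracking data.

## Problem sizes and numerical choices

Simulation-based checks run at the sizes a laptop handles comfortably:
state recovery at N ≈ 3,500 observations with 5,000 Gibbs iterations
(2,500 burn-in); sparsity and ablation at 4,000 iterations; regression
calibration at N = 2,000 with one full 4-chain fit plus 19 reduced
2-chain replicates; the end-to-end determinism run at reduced iteration
counts. Production defaults (20,000/10,000 iterations; 4 × 1000/1000
HMC) remain the package defaults. Degenerate inputs fail loudly: empty
GPS tables, duplicate timestamps, non-finite coordinates, out-of-range
counts, constant covariate columns, and all-unclassified budgets each
raise named errors. Categorical sampling uses cumulative-sum inversion
with a single uniform per observation; log-domain guards clip
probabilities at 1e-300; simplex draws renormalize gamma variates
directly. All randomness flows from explicit integer seeds; reruns are
byte-identical.

## Known limitations

* The mixture ignores temporal dependence; runs of the same behavior are
  modeled as independent draws. A hidden-Markov extension is out of scope.
* State counts and assignments inherit label-free MCMC averaging; within-
  chain label switching is not corrected (with well-separated states and
  a sticky sampler it does not occur in practice, and all reported
  summaries are invariant to index permutation).
* The regression treats state labels as data, ignoring classification
  uncertainty from the mixture stage.
* Buffer extraction assumes the track and raster share a projected metric
  CRS; no reprojection is attempted.
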