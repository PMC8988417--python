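# Methods

`hetsurv` quantifies how heterogeneity in the measurement of a predictor —
the same quantity measured by a different procedure in clinical practice
than in the validation study — degrades the out-of-sample performance of a
time-to-event prediction model that is implemented *as-is*. This note
records the models, conventions, and numerical choices behind the package.

## Data-generating mechanism

Cohorts are simulated from a Cox-exponential model. Each subject carries a
predictor X ~ N(0, 1) and an event time T with hazard
λ(t | x) = λ₀ · exp(β x), constant in t. Times are drawn by inverting the
cumulative hazard at a uniform draw (T = −ln U / (λ₀ e^{βx})), which is
exact for the exponential baseline. Defaults are λ₀ = 0.1 and
β = ln 2 (hazard ratio 2 per SD of the predictor), which puts the median of
the marginal event-time distribution at ≈ 6.6 time units (computed in
`marginal_median` by Gauss–Hermite quadrature of
S(t) = E_X[exp(−λ₀ t e^{βX})] and root-finding, 100 nodes — accurate far
beyond the reported decimal).

Three censoring regimes:

- **none** — all events observed;
- **administrative** — follow-up truncated at `admin_time` (default 15);
  since the marginal median (6.6) is well below 15, the Kaplan–Meier median
  is unaffected while the event fraction drops to
  P(T ≤ 15) ≈ 74.4%;
- **random** — censoring times drawn by the same inverse-transform
  construction from an independent Z ~ N(0, 1) with baseline hazard 0.01
  and hazard ratio 3, *combined with the administrative cap*
  (observed = min(T, C, 15)). The cap is applied by default
  (`admin_cap_under_random=True`) because the analytic event fraction under
  the capped construction, 68.6%, matches the reference event fraction of
  ~69%, whereas the uncapped construction gives 85.7%. The quoted median
  follow-up of ≈ 5.6 under this regime is the median of the *observed*
  times min(T, C, 15): the Kaplan–Meier median is invariant to independent
  censoring and stays at ≈ 6.6.

RNG discipline: the master seed is split into four independent substreams
(covariates, event-time uniforms, censoring covariate, censoring uniforms)
via `numpy.random.SeedSequence.spawn`, so changing the censoring regime
never perturbs the simulated event times, and identical seeds give
bit-identical cohorts. Event/censoring ties (measure-zero in continuous
time) resolve as censored.

## Measurement heterogeneity model

The implementation-setting measurement W of a validation-setting predictor
X follows the classical linear measurement-error form

    W = ψ + θ·X + ε,   ε ~ N(0, σ_ε²),

with ψ an additive systematic shift, θ > 0 a multiplicative systematic
association, and σ_ε the SD of additional random variation (the
implementation measurement is assumed *noisier* than the validation one;
deconvolution toward a less noisy measurement is out of scope). ε is drawn
fresh on every call from its own seeded substream, so bootstrap procedures
can either propagate measurement randomness (default) or freeze it.

Scenario grids are full factorials of equally spaced levels per parameter,
endpoints included; 3 levels over the default ranges ψ ∈ [−0.3, 0.3],
θ ∈ [0.5, 2], σ_ε ∈ [0, √2] give the 27-scenario design. Equal spacing was
chosen over ratio-symmetric θ levels (0.5, 1, 2) as the plainer default —
the factorial construction accepts any ranges and level count, so either
design is one call away. Note that with equal spacing the default θ levels
are (0.5, 1.25, 2): the homogeneity triple (0, 1, 0) lies on the grid only
when each range is symmetric about its null value.

## Survival models and prediction

A model is a `ModelSpec`: named log-hazard-ratio coefficients, a baseline
survival S₀ (an exponential rate or a right-continuous step function), and
per-predictor centering offsets. Predictions are
S(t | x) = S₀(t)^{exp(LP)}, LP = Σ βⱼ(xⱼ − cⱼ).

- **Exponential PH fit**: exact maximum likelihood via the Poisson-GLM
  equivalence (event indicator regressed on predictors with log follow-up
  as offset, `statsmodels`). The intercept exponentiates to λ₀.
- **Cox fit**: partial likelihood via `lifelines.CoxPHFitter` (Efron tie
  handling — ties are measure-zero in the simulations, Efron is the safer
  default on real data), with the baseline estimated by a hand-rolled
  Breslow estimator so that linear predictors can enter as fixed offsets.
- **Centering**: off by default (`centering_offsets = 0`) — models
  published for clinical use are rarely centered, and centering shrinks
  the apparent impact of additive measurement shifts; a `center=True` flag
  centers at the fitting data's predictor means.
- **Baseline convention**: S₀ is right-continuous and constant between
  event times; evaluation beyond the last follow-up time in the estimation
  data raises by default (`extrapolation="clamp"` holds the last value).
- **External models** can be constructed directly from published
  coefficients and a supplied baseline without refitting.

`recalibrate_baseline` re-estimates the Breslow baseline on a new cohort
with each subject's LP as a fixed offset, leaving coefficients untouched —
the standard "update of the baseline survival" for a model found
miscalibrated in the large. The update equates observed and model-expected
*event counts* at every event time; consequently O/E returns to ≈ 1
whenever the miscalibration lives in the baseline (any multiplicative or
shape distortion of S₀). If the coefficients themselves are badly wrong, a
Jensen-type gap between mean survival probability and expected counts
remains and recalibration-in-the-large cannot (and should not) hide it.

## Performance battery

All metrics are evaluated at a fixed horizon t (default 6.5, roughly the
median survival time):

- **O/E ratio** — observed vs expected *event probability*:
  (1 − S_KM(t)) / (1 − mean predicted S(t)). The package defaults to the
  event-probability form because it is the one whose interpretation is
  standard (O/E < 1 ⟺ predicted risks too high on average); the
  survival-probability ratio S_KM(t)/mean S(t) is available via
  `form="survival"`.
- **AUC(t)** — cumulative/dynamic: cases have an event by t, controls are
  observed beyond t. Censoring is removed by IPCW using the reverse
  Kaplan–Meier curve G: case i weighted 1/G(tᵢ⁻) (left limit), every
  control weighted 1/G(t) — the standard Uno-type estimator. Marker ties
  count ½. The implementation sorts controls once and uses cumulative
  counts (O(n log n)), and is pinned to an explicit pairwise double-loop
  oracle to 10⁻¹² in the tests; with no censoring it reduces exactly to
  the Mann–Whitney AUC of 1{T ≤ t}.
- **Brier(t)** — IPCW-weighted squared error: events by t contribute
  S²/G(tᵢ⁻), subjects beyond t contribute (1 − S)²/G(t), subjects censored
  before t contribute 0; divisor n.
- **IPA(t)** — 1 − Brier_model/Brier_null with the null model predicting
  the Kaplan–Meier marginal risk for everyone; 1 = perfect,
  0 = uninformative, < 0 = harmful. The identity is enforced structurally
  (`MetricsResult.ipa` is derived from the two Brier scores).

Kaplan–Meier and reverse-KM estimation use `lifelines`; left limits are
evaluated on the extracted step function. Bootstrap CIs are percentile
intervals over subject resamples (default B = 500, 95%), chosen over BCa
as the plainer method; a fixed seed makes them reproducible.

## Quantitative prediction error analysis

`run_scenarios` evaluates the *unchanged* model on the validation cohort
with the flagged predictor replaced by W under each scenario, computing
the full battery with bootstrap CIs. Each scenario draws from a
deterministic substream `SeedSequence((seed, scenario_index))`, so results
are independent of evaluation order. Within the bootstrap the measurement
noise ε is redrawn per resample by default, propagating measurement
randomness into the CIs; `freeze_epsilon=True` conditions on one draw.

`marginalize` collapses the scenario table per σ_ε level: the inner band
is the (min, max) of point estimates across the ψ×θ sub-grid, the outer
band the envelope of the bootstrap CIs. The range (not the average) over
the systematic-heterogeneity sub-grid is reported because the analysis
question is "how bad could it plausibly get", not "what is the typical
scenario". `render_report` writes the scenario table, band table, one
figure per metric (bands vs σ_ε with the homogeneity reference line), and
a seven-step report skeleton whose narrative fields (prediction target,
measurement comparison, literature-informed ranges) are analyst-supplied
text — those steps are human activities the tool records but cannot
automate.

## Synthetic example cohort

`generate_example_cohort` emulates the *shape* of a realistic validation
dataset for a chronic-disease (type-2 diabetes) risk model: 15,464
subjects, four positively correlated continuous predictors (age, BMI,
triglyceride, fasting glucose; equicorrelation 0.2 — the real correlation
structure is not public, so this default is synthetic and configurable),
exponential PH event times, staggered-entry uniform censoring capped at 6
years, and a baseline hazard solved by Brent root-finding so the expected
observed-event count hits a target (default 192, giving a ~1.2% event
fraction). It exercises the full workflow at realistic scale and sparsity;
it does not reproduce any real dataset's estimates, and nothing in the
package's verification depends on its particular coefficient values.

## What the simulations do and do not show

The generator realizes the idealized study conditions: a single
standard-normal predictor, a correctly specified proportional-hazards
model, no overfitting, no difference in case mix, event rate, outcome
measurement or treatment policy between settings. Passing tests therefore
demonstrate the measurement-heterogeneity mechanism in isolation; on real
data the same analysis confounds with all of the above, and heterogeneity
in several correlated predictors at once is explicitly out of scope.

## Problem sizes and tolerances

Reference-scale checks use n = 10⁶ (benchmark metrics, censoring
fractions), n = 5×10⁵ per heterogeneity scenario for the qualitative
response-surface checks, 50 replicates of n = 10⁴ for estimator recovery,
and n = 10⁵ for the recalibration contract; unit tests run at n = 5×10⁴
and below with tolerances set from the corresponding Monte-Carlo standard
errors (3–4 σ). Oracle comparisons (closed forms, brute-force IPCW sums)
are asserted to 10⁻¹²; bit-level reproducibility is asserted exactly.
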