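# Methods

## Setting and estimands

Each analysis unit is one meal of one person with type 1 diabetes wearing a
CGM and an insulin pump. The treatment `Z` is the meal's carbohydrate
content (grams); the mediator `M` is the total bolus insulin (units)
delivered in the closed window [−120, +60] minutes around the meal; the
outcome is the glucose excursion `ΔG(t) = G(t) − G(0)` (mg/dL) at horizons
t ∈ {60, 90, 120, 150, 180, 210} minutes, with `G(0)` the CGM reading at
the (grid-snapped) meal time.

For a contrast from the meal-type median dose `z0` to `z1 = z0 + δ`
(δ ∈ {15, 30, 45} g), the counterfactual decomposition is

    ACME(z) = E[ Y(z, M(z1)) − Y(z, M(z0)) ]        (through insulin)
    ADE(z′) = E[ Y(z1, M(z′)) − Y(z0, M(z′)) ]      (all other pathways)
    Total   = ACME + ADE                             (exact, per draw)

reported as the average of the two z-specific versions. Identification
rests on sequential ignorability: treatment ignorable given the pre-meal
state, and mediator ignorable given treatment and pre-meal state. The
pre-meal state is summarized by learned embeddings (below); the assumption
itself is untestable and is operationalized, not proven, by the balancing
machinery.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes — it
is not an insulin PK/PD simulator. Per meal, a latent state `U` (standard
normal, 2-dimensional by default) drives everything:

* pre-meal glucose: AR(1) (coefficient 0.9, innovation SD 5 mg/dL) around
  a level `145 + (12, 6)·U` mg/dL, so `U` is recoverable from the pre-meal
  window (a *measured* confounder in the identification sense);
* treatment: `Z = median(meal type) + 20·(0.4·U₁ + √(1−0.4²)·ε)` g,
  truncated positive. The 0.4 makes balancing necessary but feasible.
  Default medians (breakfast/lunch/dinner/snack = 47/65/63/27 g) follow
  typical T1DM study meals;
* mediator: `M = max(0, α₀ + a·Z + γ·U + ε_M)`, a left-censored bolus with
  `a = 0.1` U/g (a 1:10 insulin-to-carbohydrate ratio), `σ_M = 2` U, and
  `γ = (0.6, 0.3)`. `alpha0_for_zero_fraction` solves for the intercept
  that yields a target zero-bolus rate, accounting for the positivity
  truncation of `Z` through truncated-normal moments;
* outcome: `ΔG(t) = c(t)·Z + b(t)·M + κ·U + ε_Y(t)` with `c(t)` peaking at
  120 min (0.49 mg/dL per g), `b(t)` most negative at 120 min
  (−3.2 mg/dL per U), `κ = (8, 4)` mg/dL and `σ_Y = 22` mg/dL. Meal-type
  modifiers scale (a, b, c): amplified but nearly cancelling pathways at
  breakfast, an under-compensated direct effect at dinner, weak coupling
  at lunch and snack. The post-meal CGM trace is built through these exact
  excursion values at the six horizons (monotone-spline interpolated in
  between, washing out to the baseline process by +240 min), so window
  extraction recovers the structural equation exactly.

Meals sit on four daily slots 360 minutes apart with ±7 min off-grid
jitter; gaps (geometric length) and artifact spikes are injected at
configurable rates. By default effects enter as a location shift, so all
conditional quantiles share one truth and the mean and quantile models
must agree; a scale-shift option (`scale_shift_coef`) makes the noise SD
grow with `Z` for genuine quantile heterogeneity. Boluses materialize as a
single event at meal time (a split-event option exercises aggregation).

Because the latent mean of `M` at dose z (with U at its mean) is
`μ_z = α₀ + a·z`, the implied true effects are closed-form:

    true_ACME(t, δ) = b(t) · (E max(0, N(μ_z1, σ_M²)) − E max(0, N(μ_z0, σ_M²)))
    true_ADE(t, δ)  = c(t) · δ,     E max(0, X) = μΦ(μ/σ) + σφ(μ/σ).

These oracles are cross-checked against 10⁶-draw brute force in the tests.

Known departures from real CGM data: no sensor drift or compression
artifacts, no overnight basal dynamics, no meal-composition effects
(glycemic index), no autocorrelated outcome noise across horizons, and a
post-meal trace that is smoother than a real sensor's. Passing tests
therefore demonstrate correctness of the estimation machinery under the
assumed structural model, not robustness to physiological model
misspecification.

## Preprocessing

CGM gaps of at most five consecutive readings with observed flanks are
linearly interpolated; longer or boundary gaps stay missing. Windows span
[−120, 0) (24 grid rows × 5 channels: glucose, steps, basal rate, a sparse
carbohydrate channel, heart rate) through +210 minutes. Exclusions: meals
under 90 minutes from a neighbour (both members dropped), any unimputed
missing reading in [−120, +210] (strictest reading; threshold
configurable), artifact readings (outside 20–500 mg/dL or a jump above
50 mg/dL per 5 minutes — our operationalization), and any bolus in
(+60, +210] (a bolus at exactly +60 belongs to the mediator window). Meal
times snap to the nearest grid point, ties rounding down. The first
⌈0.65·days⌉ days of each subject form the training partition;
standardization statistics come from training windows only.

## Embeddings (causally-constrained autoencoder)

A three-block 1-D CNN (32/64/128 filters, kernel 3, max-pool stride 2,
global average pooling; bolus deliberately absent from the inputs to avoid
mediator leakage) is concatenated with the five per-channel means and
projected to φ ∈ R⁸. Four heads predict from φ: the flattened pre-meal
matrix (weight 0.5), the mediator (0.5), the excursion trajectory at the
six horizons (2.0), and the treatment (weight 0 by default — kept only as
an ablation axis, since predicting treatment directly opposes balance).
Regularization: L2 10⁻⁴ in the loss, decoupled decay 10⁻⁵ in the
optimizer, dropout 0.2, input noise SD 0.05, gradient-norm clipping at
1.0, batch 32. AdamW (lr 10⁻³) is the default; RMSprop is available as a
config switch. An "lstm"-slot encoder is provided as a minimal 64-unit
tanh-RNN stub for the architecture ablation only.

Four penalties act on the embeddings:

* **balancing** (γ = 2.0): squared mean gap plus squared Frobenius
  covariance gap between φ of higher- and lower-carbohydrate meals (split
  at the per-meal-type training median);
* **conditional independence** (λ = 0.05): squared correlation between the
  residuals of Z and M after in-batch least squares on the basis expansion
  ψ(φ) = φ + g(φ) (g a small two-layer residual map);
* **linearizability** (λ = 0.1): MSE between the nonlinear outcome head
  and the best in-batch linear map of φ to the outcome targets;
* **stability** (λ = 0.01): Frobenius distance between the φ covariance
  matrices of two stochastic forward passes.

All four are differentiable and exactly zero at their degenerate case.
**Scale invariance.** The raw moment-gap forms can be minimized by
shrinking φ's scale without removing treatment information (we observed
exactly this: embedding SDs collapsed while treatment correlations were
unchanged). The training loop therefore evaluates the balancing and
stability penalties on batch-standardized embeddings (per-dimension
z-scores); the penalty functions themselves keep the stated formulas.

Training is float64, single-threaded numpy with a hand-written
reverse-mode autodiff engine (gradients verified against central finite
differences), which makes runs bit-reproducible for a fixed seed.

Validation metrics on held-out windows: outcome R² (trajectory head),
mediator R², balance score `1 − mean_d |corr(φ_d, Z)|` (the score
definition is ours), and in-range AUC for the 70–180 mg/dL band. For the
AUC, the per-horizon score is the negative distance of the predicted
glucose value from the band (zero inside), so a perfect head separates
perfectly; using the raw predicted value as a score would be non-monotone
in band membership.

The finite-sample ceiling of the balance score is not 1: with n windows
and independent embeddings, `E|corr| ≈ √(2/πn)` per dimension (≈ 0.95 for
n ≈ 250). The ablation harness trains each penalty configuration over
several seeds and selects by covariate balance subject to adequate outcome
prediction (mean R² within 0.1 of the best; an absolute margin, because a
relative one degenerates when R² is near zero).

PCA is fit on training φ only; presets keep k = 3 components (mediation
covariates) and k = 6 (balancing covariates).

## Balancing weights

Weights for the continuous treatment solve an entropy-balancing program:
maximize Σ −w log w subject to mean-one weights and zero weighted means of
each covariate, of Z, and of every Z·covariate product (all standardized)
— the last block enforcing weighted decorrelation. The dual is smooth and
convex (log-mean-exp); it is solved by Newton trust-region with analytic
gradient and Hessian, and constraints are checked to a 10⁻⁶ residual.
Perfect Z–covariate collinearity is detected and reported as infeasible
(no positive reweighting can break an exact linear tie). The balance model
uses the six leading embedding PCs plus meal-time glucose and a centered
cohort indicator; those last two never enter the mediation formulas
(collider avoidance). Weight trimming is off by default; an optional cap
renormalizes and logs when active. ESS = (Σw)²/Σw².

## Mediation models and inference

*Mediator*: Tobit regression of M on Z and the PCs — weighted
censored-normal maximum likelihood (density term for M > 0, lower-tail
mass at 0), BFGS with analytic gradient, covariance from the inverse
observed information (numerical Hessian in (β, σ)). With no zeros the fit
reduces to weighted least squares (verified to 10⁻⁶); with all zeros it is
rejected. The Tobit is fit with the balance weights by default (a flag
disables this).

*Outcome*: per horizon, either (a) a weighted random-intercept linear
mixed model, fit by profiled ML over the two variance parameters with the
per-subject marginal covariance `σ_e² diag(1/wᵢ) + σ_b² 11ᵀ` handled by
Woodbury/determinant-lemma identities (matches statsmodels MixedLM in the
unweighted case), or (b) weighted quantile regression at τ ∈ {0.25, 0.5,
0.75}, solved exactly as a linear program (HiGHS), with coefficient
covariance from a subject-level bootstrap (default 200 resamples; the
resampling unit is the whole subject, respecting within-subject
correlation).

*Quasi-Bayesian engine*: for each of n_sims (default 1000) draws,
mediator and outcome parameters are sampled from normal approximations at
the estimates with the fitted covariances (Cholesky; a ridge is added with
a warning if singular; σ is floored at 10⁻³). Potential mediators
`M(z) = max(0, x(z)β_m + σ_m ε)` are simulated per analysis unit with
fresh noise — the noise matters because censoring makes E[M(z)] nonlinear
in the linear predictor. Counterfactual outcomes are the model-implied
means at the four (z, M(z′)) combinations: outcome-level noise is not
re-added (it cancels in expectation for these contrasts and would only
inflate Monte-Carlo variance), and random intercepts are set to zero
(population-averaged effects). Point estimates are means over draws, 95%
intervals are 2.5/97.5 percentiles, and p-values are doubled Monte-Carlo
tail fractions, floored at 1/n_sims and capped at 1. Total = ACME + ADE
holds exactly in every draw.

The full suite covers {pooled, breakfast, lunch, dinner, snack} × six
horizons × three doses × four outcome models (≤ 360 cells). Anchors z0 are
per-meal-type medians of the analysis sample; the pooled stratum uses each
window's own meal-type median, so "+30 g" always means +30 g above that
meal's typical size. Strata under 20 windows (configurable) are skipped
and logged. No multiple-testing adjustment is applied across cells.

## Problem sizes and numerical choices

Default study scale is 12 subjects × 56 days × 4 meals (≈ 2700 meals).
The validation experiments use sizes chosen to make Monte-Carlo error
small relative to their tolerances: oracle-recovery fixtures n = 2000
with σ_M = 1.5, σ_Y = 4 (several estimator SEs inside the ±0.5 band);
censored-mean checks at 10⁶ draws; Tobit recovery at n = 2000 over 20
replicates; coverage at 100 replicates of n = 800 with 300 draws;
the penalty ablation on a 16-subject × 40-day cohort at 10 epochs with
three seeds. The shortened ablation training is deliberate: at this data
size longer unconstrained training overfits (large train R², negative
test R²), and the comparison would measure memorization rather than
information content.

Ties and degenerate inputs: constant channels standardize to themselves
(SD clamped to 1); constant residuals zero the conditional-independence
penalty; constant prediction floors R² at 0 with a warning; an AUC over a
single class is NaN; quantile-LP failures inside the bootstrap are dropped
with a warning if too frequent.

## Limitations

* Balancing embeddings removes treatment-correlated confounder
  information by construction, so outcome-model adjustment loses exactly
  the confounder directions that correlate with Z; mediator-outcome
  confounding through those directions is handled by the weights, not the
  PCs. On strongly confounded synthetic data the ACME point estimate is
  attenuated toward zero relative to truth while signs and ordering are
  preserved — an inherent property of the design, visible in the analysis
  drivers.
* The quasi-Bayesian normal approximation can be poor in tiny strata
  (the floor of 20 windows is a guard, not a guarantee).
* The generator's location-shift default makes quantile models agree with
  the mean model; it cannot by itself validate discovery of real quantile
  heterogeneity (use the scale-shift mode for that).
* Single-threaded CPU only; the autodiff engine implements exactly the
  operations this architecture needs and is not a general-purpose
  framework.
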