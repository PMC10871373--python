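# Methods

`neurochron` implements, end to end, an analysis chain linking striatal
dopamine dynamics measured by fast-scan cyclic voltammetry (FSCV) to human
temporal-bisection performance, together with a synthetic-data generator
that provides ground truth for every stage. Because no public patient
recordings exist, every empirical claim the package makes is a
*parameter-recovery* or *calibration* claim about synthetic data whose
generative structure mirrors the study design: 6 patients, 300 bisection
trials per session, anchors at 0.5 s and 1.1 s, FSCV features sampled at
10 Hz, dopamine and serotonin decoded jointly.

## Generative model

**Task.** Probe durations form a 7-level linear grid spanning the anchors
(0.5, 0.6, …, 1.1 s). Trials are assigned to levels as evenly as possible;
since 300 is not divisible by 7, the remainder is placed symmetrically
about the 0.8 s midpoint (counts 43, 43, 43, 42, 43, 43, 43), preserving
the symmetry of the duration marginal. Onsets follow jittered inter-trial
intervals (5 ± 1 s uniform) snapped to the 10 Hz sample grid, so epoch
extraction incurs no interpolation error at default settings.

**Neurochemistry.** The ground-truth dopamine series is the sum of

* a *tonic* component: a Gaussian random walk reflected at 0 µM
  (|Brownian| is a reflected Brownian motion), step SD 0.008 µM at 10 Hz
  around a 1 µM mean. This yields drifts on the order of a few tenths of a
  µM between adjacent 4-minute windows and ~1 µM over a 25-minute session
  — the magnitude of tonic fluctuation human FSCV studies report, and
  large enough relative to decoder noise that tonic recovery is a
  meaningful test;
* *phasic* transients: one causal exponential kernel per trial,
  `amp * exp(-(t - onset - latency)/tau)` for `t >= onset + latency`, with
  amplitude ~ N(0.2, 0.05) µM truncated at 0, latency 0.6 s and decay
  constant tau 0.2 s. The latency places the kernel peak at stimulus
  onset + 600 ms, so the response-conditioned contrast is maximal around
  the 625–670 ms analysis window.

Serotonin carries an independent tonic walk and, by default, no
stimulus-locked transients (transient parameters for serotonin are
exposed for specificity experiments). Sweep features are a linear mixture
of two unit-norm Gaussian-bump template vectors (32 features; dopamine and
serotonin bumps at different sweep positions, partially overlapping) plus
a linear drift (1e-4 feature-units/s) and i.i.d. Gaussian feature noise
(SD 0.1 µM-equivalent). Electrochemical realism beyond
mixture + drift + noise (pH transients, fouling, background subtraction)
is deliberately out of scope.

**Observer.** Responses come from a cumulative-Gaussian bisection
observer: `P('long'|d) = lapse/2 + (1-lapse) * Phi((d - bp)/sigma)`. Two
couplings tie behaviour to neurochemistry:

* *phasic*: `bp_trial = bp_true + phasic_coupling * z(amp)`. Positive
  coupling makes high-transient trials more likely to be judged 'short',
  i.e. a temporal underestimation bias, which is the behavioural direction
  the analysis chain is built to detect (the dopamine coefficient in the
  trial-level logistic model, with 'long' coded 1, is then negative).
* *tonic*: `sigma_trial = sigma_true * exp(-tonic_coupling * z(tonic at
  onset))`. The multiplicative form keeps sigma positive and makes the
  precision outcome used downstream, −log(Weber fraction), linear in the
  tonic level. Positive coupling means higher tonic dopamine → better
  precision.

Coupled-cohort defaults are `phasic_coupling = 0.08` s per z-unit and
`tonic_coupling = 0.3` per z-unit: large enough that a 6-patient cohort
recovers the signs reliably, small relative to sigma (~0.12 s) so
single-trial behaviour remains stochastic.

**Seeding.** A single master seed spawns independent `SeedSequence`
substreams per component (trial order, ITI jitter, tonic walks, transient
amplitudes, sweep noise, behaviour). Outputs are bit-identical across
reruns, and skipping sweep synthesis (`include_sweeps=False`, used by
behaviour-only simulations) does not perturb the behavioural stream.

## Decoding

Concentrations are decoded by penalized linear regression trained on
synthetic in-vitro-style calibration data (full factorial of a
concentration grid for both analytes, cycled and shuffled). One elastic
net per analyte shares a single (l1_ratio, lambda) pair selected by
k-fold cross-validation on the summed dopamine + serotonin MSE
(default grids: l1_ratio ∈ {0.1, 0.5, 0.9}, lambda log-spaced over
1e-6…1e-1, 10 folds); standardization constants are computed from training
folds during selection and from the full set at the final refit. The
penalty uses the scikit-learn `ElasticNet` convention, so `l1_ratio = 0`
has the closed-form ridge solution `(X'X + n·lambda·I)^-1 X'y` on
standardized features, which the tests exploit as an exact oracle.
Decoded estimates are affine in the sweep features and may be negative;
no clipping is applied because all downstream analyses use relative
changes.

## Decomposition

* *Tonic*: sliding-window means, default 240 s non-overlapping windows
  (120/240/360 s swept in robustness tests).
* *Phasic*: stimulus-locked epochs on a fixed grid from −0.5 to +1.1 s
  around onset, baseline-corrected by subtracting the per-trial mean over
  [−0.5, 0) s. A z-scoring mode is provided as an alternative
  normalization; baseline subtraction is the default event-locked
  convention and makes pre-stimulus traces start at zero. Trials whose
  epoch would leave the recording are dropped with a logged count.
* *Window summaries*: the per-trial mean over a post-onset window,
  default 625–670 ms. Because that window does not align with the 100 ms
  grid, samples are weighted by the overlap of their coverage interval
  [t − Δ/2, t + Δ/2) with the window (at 10 Hz: the 0.6 s and 0.7 s
  samples with weights 25/45 and 20/45). This rule is deterministic,
  linear, reduces to exact sample means for grid-aligned windows, and is
  cross-checked in tests against brute-force integration of the
  sample-and-hold step function. A nearest-sample mode exists as a
  fallback.

## Psychometrics

Cumulative-Gaussian psychometric functions are fitted by maximum
likelihood (L-BFGS-B, bounds bp ∈ [0.4, 1.2] s, sigma ∈ [1 ms, 0.6 s],
five deterministic starts, ties broken toward smaller sigma). The lapse
rate is fixed at 0 by default and can be fixed elsewhere or estimated
(bounded [0, 0.5]). Derived indices follow the conventional bisection
definitions: JND = half the 25–75% interquartile span = Φ⁻¹(0.75)·sigma ≈
0.6745·sigma; Weber fraction = JND/BP. Perfectly separable data drive
sigma to its lower bound and are flagged non-converged. Grouped fits
(`indices_by_group`) fit each label independently in order of first
appearance and flag groups under 20 trials.

## Cluster-based permutation testing

Per participant and epoch timepoint, a Welch t contrasts
response-conditioned trial groups; the signed statistic is mapped to a
z-value through the probit of its one-sided Student p and combined across
participants by Stouffer's method with equal weights (this accommodates
unequal trial counts and is exchangeable under within-participant label
permutation). Clusters are maximal runs of |z| above the two-sided
threshold Φ⁻¹(1 − α/2) (α = .05 default); the cluster statistic is the
mass ∑|z|. The familywise-corrected p-value of each observed cluster is
its rank against the permutation null of the *maximum* cluster mass
(default 1000 permutations, labels permuted independently within
participant), with the +1 correction `(1 + #{null ≥ mass})/(1 + n_perm)`.
Type-I calibration is verified by simulation (≤ 7.5% of 200 null cohorts
produce any p < .05 cluster).

## Inference models

* *Terciles*: within-participant rank split of the cluster-window
  dopamine summary into low/medium/high with group sizes differing by at
  most one (larger groups at the low end), stable tie-breaking by trial
  order, hence invariance to monotone transforms.
* *Trial-level logistic and tercile models*: random-intercept logistic
  regressions of the 'long' response on standardized duration plus either
  the standardized dopamine summary or the tercile code (−1/0/+1). The
  random intercept is integrated by adaptive Gauss–Hermite quadrature
  (15 nodes centred at the per-participant Laplace mode with curvature
  scaling); the marginal likelihood is maximized over fixed effects and
  log random-intercept SD, and standard errors come from the numerical
  Hessian. The implementation is verified against a dense-trapezoid
  integration oracle and, for a single participant, reduces exactly to
  ordinary logistic regression. Only random intercepts are modelled —
  six participants cannot support richer random-effect structures.
* *Tonic outcome models*: linear mixed models (statsmodels `MixedLM`,
  ML, random intercepts) of a per-tonic-window psychometric outcome on
  the standardized window tonic level. Precision is coded −log(Weber
  fraction) so "better precision" is increasing and residuals are closer
  to Gaussian; accuracy is the window BP. Both outcome and predictor are
  z-scored, so coefficients are standardized. Non-converged window PF
  fits are excluded (logged); a degenerate random-effects fit falls back
  to a fixed-intercept (within-participant) estimator and is flagged
  non-converged. p-values use the normal reference on z = β/se — a
  small-sample approximation at n = 6 participants, which is why the test
  suite checks CI calibration by simulation rather than trusting nominal
  levels.

## Bayesian statistics

* *Prevalence*: with k of n participants individually significant at
  level α, the likelihood is Binomial(k; n, θ), θ = α + γ(1 − α), uniform
  prior on the prevalence γ. The posterior is evaluated on a 1e-4-step
  grid; the MAP has the closed form max(0, (k/n − α)/(1 − α)); the 96%
  highest-posterior-density interval (the method's conventional reporting
  level, configurable) is found by shortest-interval search on the grid
  and verified against a 10× finer grid.
* *Bayes factors*: the two-sample JZS t-test Bayes factor (Cauchy prior
  on the standardized effect, scale √2/2) is computed by adaptive
  quadrature of the g-prior mixture integral and verified against a
  1e6-point trapezoid oracle and an independent reference implementation;
  regression Bayes factors use the BIC approximation
  `bf10 = exp((BIC0 − BIC1)/2)`, with the method recorded in the output so
  the approximation is explicit.

## Pipeline

`run_pipeline(RunConfig)` executes simulate → calibrate/decode →
decompose → psychometrics → cluster test → mixed models → prevalence in
dependency order; disabling an upstream stage makes dependents fail fast
naming the missing stage. The report JSON carries a config hash and the
master seed, and reruns are bit-identical. The prevalence stage counts
participants whose own trial-level logistic dopamine coefficient is
significant at α = .05.

## Problem sizes and numerical choices

Validation simulations use: 50 sessions for BP recovery, 100 sessions per
group value for JND recovery, 200 six-patient null cohorts at 500
permutations for cluster type-I calibration, and 25 coupled six-patient
cohorts for end-to-end sign recovery — sizes at which the Monte Carlo
error of each check is well below its tolerance. Degenerate inputs are
handled explicitly: collinear analyte templates are rejected; constant
features are dropped from the decoder with a warning; zero-variance
predictors raise; all-equal tercile bases fall back to a stable
trial-order split with a warning.

## What passing tests do and do not show

The generator emulates the *statistical structure* the analysis assumes —
linear sweep mixtures, slow tonic drift, stimulus-locked transients, a
cumulative-Gaussian observer with dopamine-coupled bias and precision. It
does not emulate electrochemical artefacts, non-stationary electrode
sensitivity, attention lapses correlated over time, sequential response
dependencies, or model mismatch in the psychometric form. Passing
recovery tests therefore demonstrates that the pipeline is correct and
well-calibrated under its own assumptions; they cannot certify
sensitivity or specificity on real intracranial recordings, and effect
sizes estimated from real intracranial recordings are not reproduced
here.
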