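# Methods

## Progression model

Disease state is a time-homogeneous continuous-time Markov chain (CTMC) on
the ordered states NC (1), aMCI (2), AD (3). The default transition
structure allows NC→aMCI, aMCI→NC and aMCI→AD; AD is absorbing and the
direct NC→AD jump is structurally excluded — between roughly annual
visits such jumps are essentially never observed, and the two-step path
still gives P_{NC,AD}(t) > 0 for every t > 0, which the test suite
asserts. Intensities are covariate-proportional,
q_ab(V) = r0_ab·exp(β_abᵀV), with V a patient-specific, time-constant
covariate vector by default (a time-varying V can be emulated by
splitting a subject's record, but nothing in the package does this
automatically). Transition rates are not time-dependent: no age-of-process
inhomogeneity, no hidden-state misclassification, no exact-onset-time
observations. Those extensions are out of scope.

### Likelihood and fitting

Panel observations interval-censor the process, so a subject contributes
the product of consecutive-visit transition-probability entries of
P(Δt) = exp(ΔtQ(V)); the first-visit factor is taken as 1, i.e. the
likelihood conditions on the first observed state rather than positing an
initial distribution — standard panel-data practice when entry diagnosis
defines the cohort. An observed transition that is impossible under the
structure (e.g. AD→NC) yields −∞ with an explicit warning; genuine
round-off underflow is distinguished from structural impossibility by
clipping probabilities at 1e−300 before the log.

Optimization is BFGS on the unconstrained parameterization
(log r0, raw β). Covariates are internally z-scored for the optimizer —
age on its raw scale makes the Hessian badly conditioned — and estimates
and the observed-information covariance are mapped back to the raw scale
through the (linear) reparameterization. Convergence accepts scipy's
success flag or a residual max-gradient below 1e−3 on the standardized
scale; finite-difference gradients cannot reliably reach tighter
thresholds, and the accepted iterates agree with much longer runs to well
inside a standard error. Initial rates are observed transition counts
divided by total follow-up, floored at 1e−3/yr (a transition never
observed between consecutive visits triggers a warning and may sit near
this floor); β starts at 0. Standard errors come from the numerically
differentiated observed information at the optimum.

The matrix exponential is scipy's scaling-and-squaring `expm`. For
likelihood evaluation, intervals sharing a covariate row reuse one
eigendecomposition of Q and propagate all interval lengths at once,
falling back to per-interval `expm` when the eigenbasis condition number
exceeds 1e8 (near-defective Q). An independent truncated uniformization
series lives in the test suite and pins both routes to 1e−8.

### Onset prediction

P(AD at horizon h | state now, V) is the (state, AD) entry of
exp(h·Q(V)); it is nondecreasing in h because AD is absorbing, and the
tests check it against a 20,000-path forward simulation.

## Synthetic cohort generator

The generator defines the study conditions for every downstream test.

* **Groups and demographics.** 34 aMCI / 47 AD / 39 NC subjects
  (120 total); age ≈ 69.5 ± 8.8, 69.7 ± 9.3 and 68.5 ± 7.1 years, male
  fractions 13/34, 20/47 and 18/39, MMSE 26.6 ± 2.5, 16.1 ± 7.3 and
  28.5 ± 1.4 — a three-group memory-clinic profile in which age and sex
  are deliberately balanced and cognition is not.
* **True rates.** NC→aMCI 0.08/yr, aMCI→NC 0.05/yr, aMCI→AD 0.15/yr.
  The conversion rate sits in the commonly cited 10–20 %/yr range for
  amnestic MCI; incidence and reversion values are plausible for a
  70-year-old clinic population. Coefficients default to zero (covariates
  are carried but inert) and apply to covariates on their drawn scale
  when set.
* **Visit schedule.** 4 visits at i.i.d. Uniform(0.75, 1.25)-year gaps —
  annual follow-up with scheduling jitter. Each subject starts in their
  diagnostic group's state.
* **Paths** are simulated with the Gillespie algorithm (exponential
  holding times, embedded-chain jumps) and then interval-censored at the
  visit times; the generating truth is attached to the dataset for
  recovery tests.

Tract profiles emulate AFQ output: the standard 20-tract set resampled to
100 nodes. FA mean curves are a parabola 0.35–0.60 peaking mid-tract
(tract ends traverse crossing-fiber regions); MD (in 1e−3 mm²/s) a
shallow inverted parabola around 0.85. Group effects are additive shifts
confined to nodes 30–70 of the affected bundles — FA reduced in the
cingulum cingulate and right uncinate (NC 0, aMCI −0.025, AD −0.05), MD
elevated in the IFOF and forceps minor (aMCI +0.03, AD +0.06) — with
i.i.d. Gaussian node noise of sd 0.04 per metric and FA clipped into
(0, 1). Tracking failures occur only for the cingulum hippocampus
bundles, with probabilities 62/120 (left) and 32/120 (right).

What the generator does **not** emulate: spatial autocorrelation along
nodes and between neighbouring tracts, covariate-dependent profile
effects, scanner/site batch effects, and visit-dependent imaging. Passing
tests therefore demonstrate the statistical machinery is correct under
clean assumptions, not that effect sizes or classifier accuracies
transfer to real cohorts — with i.i.d. node noise, averaging 100 nodes
makes the synthetic AD-vs-NC classification essentially perfect, which
real data would not be.

## Tract statistics

Pointwise tests run per node after excluding untracked subjects and
(by default) residualizing on [1, age, sex] by OLS, re-centered to the
grand mean; testing then proceeds on the adjusted values. The alternative
— covariates inside a per-node linear model — is deliberately not the
default, to keep the adjust-then-test ordering explicit.

* Classic one-way ANOVA: F = MS_between/MS_within, df (k−1, N−k). The
  same statistic is computable from (n, mean, sd) summaries alone, and
  the two routes agree to 1e−10 by construction (tested).
* Welch: precision weights n_i/s_i², weighted grand mean, denominator
  correction and Satterthwaite-type df — the standard published form.
* Brown–Forsythe (means version): F* = Σn_i(x̄_i−x̄)² / Σ(1−n_i/N)s_i²
  with Satterthwaite denominator df; numerator df is k−1. Note:
  statsmodels' `anova_oneway(use_var="bf")` headline p-value adds
  Mehrotra's numerator-df correction; the implementation here uses the
  standard reference distribution (statsmodels' `pvalue2`), and the tests
  pin both the statistic and that p-value to statsmodels at 1e−10.

Significance along the 100 nodes is raw p < α by default — mirroring the
common practice for tract-profile displays — with Benjamini–Hochberg
across nodes behind a flag for readers who want FDR control. Tracts whose
tracking-failure fraction exceeds 0.25 are excluded before testing; the
threshold is chosen so failure fractions like 62/120 and 32/120 drop a
tract while zero-failure tracts never do, and it is configurable.

**Calibration caveat.** Under strong heteroscedasticity (sd ratio 4:1
with equal n = 30–100 per group) the Brown–Forsythe means test is
genuinely liberal — its true 5 % level is ≈ 0.065, stable in n, because
the Satterthwaite approximation to the null of its numerator does not
improve with sample size when variances differ this much. The calibration
suite therefore exercises BF at a 2:1 sd ratio (level ≈ 0.053) and Welch
at 4:1, each inside [0.04, 0.06]; the classic F is exact under equal
variances.

## Evaluation

Accuracy = (TP+TN)/(TP+TN+FP+FN), specificity = TN/(TN+FP), sensitivity
= TP/(TP+FN); a zero denominator yields NaN ("undefined"), never 0. A
precision-like variant TP/(TP+FP) is available behind `as_printed=True`
for comparability experiments with sources that define sensitivity that
way. ROC curves come from a full threshold sweep; AUC is the trapezoidal
area, identical to the Mann–Whitney pairwise probability with ties
counted ½ (pinned to a brute-force pairwise oracle at 1e−12).

The fusion harness concatenates per-subject feature blocks — `mm`
(predicted AD-onset probabilities at 1/2/5-year horizons from the
subject's current state and covariates), `dti` (node-mean FA and MD per
retained tract; untracked tracts mean-imputed), `smri` (synthetic
volumetric stand-ins, labelled as such) — z-scores columns, and runs
seeded stratified 5-fold cross-validation with a pluggable classifier
(default: scikit-learn logistic regression). The headline binary task is
AD vs NC; out-of-fold probabilities are pooled into one confusion matrix
(0.5 threshold) and one ROC per block combination. Because the `mm` block
encodes the current clinical state, AD-vs-NC with `mm` is near-perfect by
construction on synthetic data; the `dti`-only block is the informative
comparison.

## Numerical and design choices

* Times in years, 0-based at study entry; node indices 0-based inclusive;
  CSV dialect comma/UTF-8/`.`-decimal with mandatory headers.
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; pipeline stage seeds derive from the global seed
  (cohort = s, profiles = s+1, CV folds = s+3), so one integer pins the
  whole run and the output manifest's SHA-256 hashes reproduce exactly.
* Simulation sizes used by the checks: parameter recovery at 100
  replicates of 1,000 subjects × 5 visits (each parameter within 3 SE of
  truth ≥ 90 % of the time); calibration at 5,000 null replicates per
  test; sojourn/onset oracles at 10,000–20,000 paths. These sizes give
  Monte-Carlo error comfortably below the asserted margins.
* Degenerate inputs: groups with fewer than 2 values, zero within-group
  variance (Welch/BF), zero count margins (χ²), rank-deficient adjustment
  designs, single-class ROC labels and negative times/horizons all raise
  explicit errors rather than returning silent numbers.

## Known limitations

* The likelihood assumes non-informative visit times and ignores
  misclassification of the observed stage; both matter in real clinics.
* Observed-information SEs are asymptotic; with rare transitions (e.g.
  few reversions) the log-scale Wald intervals can be very wide, which
  the summary makes visible rather than hiding.
* The synthetic generator's independence assumptions (see above) make
  downstream classification optimistic by design; treat the evaluation
  harness as machinery validation, not a performance claim.
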