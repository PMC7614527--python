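# Methods

## Model and inference

The observation model is a K-state hidden Markov model on per-scan ICA
component time courses. States share a single covariance matrix Σ and differ
only in their mean activation vectors μ_k (z-units of the standardized time
courses); the latent chain has initial distribution π and row-stochastic
transition matrix A. Scans are z-scored per component within scan (sample
SD, ddof = 1) and temporally concatenated; the forward–backward recursions
restart at every scan boundary, so π is informed by one observation per scan
and no transition is counted across subjects.

Fitting is maximum-likelihood EM (Baum–Welch), not the variational-Bayes
scheme of toolbox implementations of the same model family. The choice is
deliberate: the downstream metrics depend only on the posteriors γ/ξ and on
A, EM is fully specified by the likelihood, and its ascent property gives a
sharp internal correctness check (the log-likelihood trace of every restart
must be non-decreasing; the test suite enforces a 1e-9 slack). No attempt is
made to reproduce toolbox-specific free energies or priors.

Numerical choices:

* scaled (normalized) forward–backward recursions, stable to T = 1e5;
* M-step covariance pooled over states,
  Σ = (1/N) Σ_t Σ_k γ_tk (x_t − μ_k)(x_t − μ_k)ᵀ, with a diagonal ridge
  ε = 1e-6 · trace(Σ)/C added each iteration for conditioning;
* initialization per restart: k-means state means (scikit-learn, seeded),
  A with diagonal 0.9 and even off-diagonal mass, uniform π, pooled sample
  covariance; 5 restarts by default, best final log-likelihood wins;
* convergence at relative log-likelihood change < 1e-5, cap 500 iterations
  (non-convergence is a warning in the diagnostics, never silent);
* state labels are arbitrary: all cross-run comparisons match states with
  the Hungarian algorithm on state-mean distances (or, against simulated
  ground truth, on occupancy correlations, which is invariant to the
  standardization of the observation space).

## Temporal metrics

All metrics are computed from soft posteriors, not Viterbi paths — the
probabilistic assignment is part of the model's reading of noisy fMRI; a
hard-path variant can be obtained by feeding one-hot posteriors.
Fractional occupancy is the column mean of γ. The switching rate divides the
expected off-diagonal transition mass by (T − 1)·TR seconds: transitions are
between-volume events, and division by true scan seconds is what makes rates
comparable across sites whose repetition times differ slightly. Whether a
"switch" should count expected (soft) or decoded (hard) transitions is not
uniquely determined by the problem; the soft count is this package's
documented choice. Per-subject transition matrices are row-normalized ξ;
rows with no expected outgoing mass are filled from the group model's A and
flagged rather than left undefined.

## Compositional PCA of occupancies

Occupancy vectors live on the simplex, so PCA is run after the
α-transformation: z = H (K u^α/Σu^α − 1)/α with H the orthonormal Helmert
sub-matrix ((K−1)×K, rows orthonormal, annihilating constants). α is fixed
at 1 (the linear case); no α-profiling is done. The number of retained
components uses the broken-stick rule (retain the leading run of components
whose variance share strictly exceeds the broken-stick expectation); an
empty leading run is forced to one retained component, flagged — downstream
models need at least one score, and a one-component solution is also the
expected outcome for a single dominant occupancy axis. Retained loadings are
varimax-rotated (no Kaiser row normalization; a single component is
unaffected either way), and rotated scores feed all later models. Loadings
are mapped back to state space as Hᵀ L for display only; scores are computed
in transform space from the training mean. The transform centers the power
term before dividing by the row sum, so the uniform composition maps to the
zero vector exactly in floating point, not just in theory.

## Cross-sectional statistics

Group contrasts on metrics and component scores use a linear mixed model
with diagnostic group, age and sex as fixed effects and scan site as a
random intercept. The model is implemented in-package by profiled REML over
the variance ratio λ = τ²/σ² (closed-form block inverses; deterministic grid
plus bounded refinement, with λ = 0 always a candidate so the model degrades
exactly to ANCOVA when the site variance estimate hits the boundary or only
one site exists). Denominator degrees of freedom are Satterthwaite-
approximated: each eigencomponent of the contrast covariance gets
ν = 2(lᵀCl)²/(gᵀAg) with g the numerical gradient of lᵀC(θ)l and A the
inverse observed REML information, pooled across the contrast's components.
The implementation is cross-checked against lme4/lmerTest in the test suite.
Age trends use orthogonalized polynomials; linear-vs-quadratic comparisons
are ML likelihood-ratio tests (1 df) with AIC reported alongside.

Transition/persistence probabilities are interdependent (rows sum to one),
so their 36 cells are tested jointly by permutation: age and sex are
residualized out of both the cell values and the permuted group indicator,
each cell's t statistic is referred to the permutation distribution of the
maximum |t| over all cells, and p values use the (1 + exceedances)/(n_perm+1)
convention — family-wise error control across every cell and both contrast
directions, with no attainable zero p. When the number of distinct
group-label splits is at most n_perm the full set is enumerated and the test
is exact. Permutations are unrestricted across sites by default;
site-blocked exchangeability can be imposed by running within strata.
Elsewhere, multiplicity is controlled by Benjamini–Hochberg FDR (step-up,
implemented directly; an independent implementation serves as the test
oracle).

Converters are compared with non-converting presymptomatic carriers at each
subject's latest presymptomatic scan passing QC (recency by visit index,
ties broken by larger volume count then scan id), using the same mixed
model with the converter flag as the group effect.

## Two-step longitudinal prediction

Stage one fits `score ~ time + (time | subject)` by REML (statsmodels
MixedLM) across all retained participants of the relevant sample and takes
each subject's annual rate of change as the fixed slope plus the conditional
(shrunken) random-slope prediction — `(time | subject)` denotes a
random-slope model, and shrinkage is inherent to that reading; single-visit
subjects are pulled toward the population slope. A singular random-effect
covariance triggers a diagonal-covariance refit with a warning. Stage two
regresses these slopes on baseline component scores (baseline = earliest
QC-passing scan) with age, sex and fixed-effect site dummies as covariates;
the three model forms add nothing, a component-by-age interaction, or the
full component-by-age-by-group factorial. All continuous stage-two variables
are z-scored within the modelled sample, so reported betas are standardized
and scale-invariant. Subjects whose baseline value sits at an outcome's
floor (or ceiling, for timed tests capped at a maximum) are removed for that
outcome only; the floor values themselves are configuration inputs, not
package constants.

## The synthetic cohort

The generator emulates a three-group, multi-site familial-dementia imaging
study and is the ground truth for every statistical claim in the test suite.
Its defaults are the study conditions: 120 non-carriers, 120 presymptomatic
carriers (14 of them converters) and 60 symptomatic carriers; 6 states on
24 components; 300 volumes per scan; base persistence 0.8; four sites with
repetition times 2.0–2.5 s; group age structure with symptomatic subjects
markedly older (63 ± 8.2 y) than presymptomatic carriers (45 ± 12 y), so
age-confounding behaviour is testable; ~10% of scans drawn to exceed a
motion-QC bound; four annual cognitive visits.

Group effects are planted mechanistically through the transition matrix
rather than through observation means: symptomatic subjects receive a
+0.078 increment to the persistence probability of a designated target
state, which raises that state's stationary occupancy from 1/6 to ≈ 0.247
(an elevation of ≈ 0.08, the planted effect size the statistics must
recover); converters receive the increment at a 50% dose — a free parameter
encoding an intermediate, late-presymptomatic phenotype, not an empirical
estimate. Annual cognitive decline in symptomatic subjects is linked to
dynamics as slope = −1.5 − 8·(true target-state occupancy − 1/6) ± 0.5
points/year with 1.0-point visit noise on an MMSE-like 0–30 scale: a
subject at the planted occupancy elevation declines ≈ 0.6 points/year faster
than average, a magnitude chosen once as clinically plausible relative to
symptomatic decline rates. Everything is bit-reproducible from the spec
seed.

What the generator does **not** emulate: autocorrelated scanner noise,
hemodynamic smoothing, spatial structure or ICA mixing errors, state-
dependent covariance changes, dropout/attrition patterns, or floor-censored
score distributions. Passing tests therefore demonstrate that the pipeline
recovers the stated effects *under the model's own assumptions* at realistic
sizes and noise — not that real fMRI satisfies those assumptions.

## Test and acceptance problem sizes

The suite checks forward–backward exactness against exhaustive path
enumeration on every (K, T) with K^T ≤ 4096; parameter recovery at 30 scans
× 300 volumes (K = 4, C = 8, persistence 0.85, 2 z-unit mean separation);
permutation-test calibration over 200 null cohorts × 500 permutations
(family-wise rejection rate within the binomial band [0.022, 0.089]); FDR
exactness on 1000 random p vectors; and planted-effect power over 50
replicates per effect (symptomatic elevation at n = 50/group detected at
FDR 5% in ≥ 90%; converter contrast sign-correct in ≥ 80% at 14 vs 150; the
occupancy-decline link sign-correct and significant in ≥ 90% at n = 60).
`scripts/acceptance.py` runs the full pipeline on the 300-subject default
cohort with 5000 permutations. These sizes are the package's reference
operating points; all are configurable.

## Known limitations

* One grouping factor (site) for the cross-sectional mixed models; nested
  or crossed random effects are out of scope.
* The permutation test handles exactly two groups; multi-group contrasts
  must be decomposed into pairwise tests.
* The shared-covariance assumption is structural: states cannot differ in
  functional connectivity, only in mean activation, matching the model
  family this pipeline implements.
* No imaging I/O: inputs are post-ICA component time courses in plain text.
* Kaiser normalization for varimax is not offered; with the broken-stick
  rule typically retaining one component it has no effect in practice.
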