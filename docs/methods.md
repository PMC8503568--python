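# Methods

## The model

The pipeline estimates *effective connectivity* — directed, model-based
influence — in a five-node resting-state network: one subcortical node
(basal ganglia + thalamus, `SubC`) and four primary sensory cortical nodes
(ventral somatosensory `vS1`, dorsal somatosensory `dS1`, auditory `A1`,
visual `V1`).  The connectivity graph is hub-and-spoke: bottom-up couplings
`SubC -> cortex`, top-down couplings `cortex -> SubC`, and an inhibitory
self-connection on every node.  Direct connections between primary sensory
cortices are anatomically implausible and are not modelled, leaving 13 free
coupling parameters for R = 5 (2(R-1) directed + R self).

Neural dynamics are linear and stationary,

    dx/dt = A x + v,

with `A[i][j]` (Hz) the influence of node j on node i.  The diagonal is
log-parameterized as `A[i][i] = -0.5 * exp(s_i)`, so a positive self
parameter `s_i` means *stronger* self-inhibition, i.e. more functional
segregation of that node from the rest of the network.  Neuronal
fluctuations `v` carry a power-law spectrum `alpha_v * omega^-beta_v` shared
across nodes.

The data feature is the complex cross-spectral density (CSD) of the BOLD
signal on a fixed frequency grid.  The model predicts it as

    S(f) = H(w) T(w) G_v(w) T(w)* H(w)* + G_e(w) I,   w = 2 pi f,

with neuronal transfer `T(w) = (iwI - A)^-1`, a per-node linearized
hemodynamic transfer `h(w) = kappa / ((iw + kappa)(iw + gamma))`
(`kappa = 0.64 e^decay`, `gamma = 0.32 e^transit`; a two-pole low-pass
surrogate for the balloon model with two log parameters per node), and a
power-law observation-noise spectrum `G_e`.  Power-law exponents are
constrained to [0, 2] through a scaled logistic.

## Data conditioning and spectral features

Each subject's T x R series is linearly detrended and divided by one common
scale (the root-mean variance across regions).  A *common* scale is used on
the model-fitting path because the generative model carries no per-region
gain: forcing every region to unit variance individually moves the data off
the model manifold and measurably degrades parameter recovery.  (Per-region
unit variance remains available and is the default of
`standardize_series`.)

CSDs are computed parametrically from a ridge-regularized multivariate
autoregression (default order 8, ridge 1e-3), which yields smooth,
low-variance spectra; a Welch segment-averaged estimator serves as an
independent oracle in tests and diagnostics, never as the fitting route.
The default grid is 32 linear points in [0.02, 0.25] Hz, truncated so the
lowest frequency completes at least 8 cycles per record.  The lower edge
deliberately excludes the steepest part of the `omega^-1` band: below
~0.02 Hz autoregressive spectral estimates of power-law processes are
systematically biased, and recovery experiments showed coupling errors
roughly doubling when the grid reached down to 1/128 Hz.

## Inversion (variational Laplace)

The Gaussian posterior over the packed parameter vector is found by damped
Gauss-Newton ascent on the free energy (accuracy minus KL complexity), with
Levenberg-Marquardt damping halved on accepted steps and doubled on
rejections, so the free-energy sequence over accepted steps is
non-decreasing by construction.  Gradients use central finite differences
(step 1e-4), evaluated in a single batched prediction per iteration.
Residual precisions are estimated jointly: one log-precision per region
pair (shared by the real and imaginary parts), prior N(0, 1), updated by
guarded Newton steps inside the same loop.  Convergence is declared when
|dF| < 1e-2 on three consecutive accepted steps (cap: 128 iterations);
non-convergence flags the subject but never excludes it.

Priors (diagonal): couplings N(0, 1/16 Hz^2); self logs N(0, 1/64);
hemodynamic logs N(0, 1/256); noise exponents N(0, 1/64); noise
log-amplitudes N(., 1/4) with the neuronal amplitude centred at 0 and the
observation amplitude at -4.  The asymmetric amplitude means encode that
cleaned BOLD carries far less measurement noise than signal — a mean-zero
observation amplitude with a tight variance forces the model to predict a
spurious white-noise floor and wrecks recovery.  Before inversion the data
CSD is rescaled once so its mean diagonal matches the prior-mean
prediction, centring the (log) amplitudes on their priors; explained
variance is invariant to this.

Explained variance is reported as 1 - SS(residual)/SS(data) over the
stacked real and imaginary CSD entries.

## Group inference (PEB / BMR / BMA)

Subjects' coupling sub-posteriors (13 parameters; noise and hemodynamics
stay first-level nuisance) enter a Bayesian second-level GLM:

    theta_i = (x_i^T kron I_K) beta + eps_i,   eps_i ~ N(0, Sigma_b),

where the first-level posterior covariances enter the likelihood, so
uncertain subjects are down-weighted.  The main design is
[mean, age, group, age x group, FD, site dummies]: age and FD z-scored,
group coded ASD = +0.5 / TD = -0.5 (the interaction then reads as the group
difference in age slope), S-1 centered dummies with the most populous site
as reference.  A within-group variant replaces the age columns by
group-masked, group-wise-centered age.  In the `orthogonalized` site mode
each dummy is projected off the age-bearing columns and off previously
processed dummies (via an incrementally built orthonormal basis), which
leaves the design's column span — and hence fitted values — unchanged while
returning the shared age/site variance to the age regressors.

`Sigma_b` is `exp(-lambda) I` with a single evidence-optimized lambda
(prior N(0, 1)) by default, or one lambda per connection
(`lambda_mode="per_connection"`, coordinate-wise evidence ascent).  The
group pipeline uses the per-connection mode: first-level estimation noise
differs strongly between self- and between-node couplings, and one pooled
component lets the noisy self-connections inflate the couplings' standard
errors.  The marginal evidence is computed in closed form (conjugate
Gaussian), so the lambda search is an exact 1-D (or coordinate-wise)
optimization rather than an inner variational loop.

Bayesian model reduction scores nested effect structures analytically from
the full posterior ("switched off" = reduced prior variance 1e-8).  The
greedy search prunes the entry whose removal most increases evidence until
no improvement, then averages over the 2^min(8, n) on/off neighborhood of
the least-decided entries with softmax(log-evidence) weights; an exhaustive
mode (capped at 2^16 models) exists for small spaces and is the oracle in
tests.

## The decision rule

An effect is *significant* when its posterior probability exceeds 0.90,
*trend* in (0.80, 0.90].  `posterior_prob` is defined as the
sign-determination probability of the moment-matched model-average
posterior, `2*Phi(|m|/sd) - 1`, which makes three statements exactly
equivalent by construction: P > 0.90, the 90% credible interval
`m +/- 1.6449 sd` excludes zero, and the significant flag.  The BMR
retention probability (summed weight of models keeping the effect) is
reported alongside as `retention_prob`; it is the natural model-space
quantity but cannot be made constructively equivalent to the interval rule,
which the reporting contract requires.

## Symptom association

For the SRS stage the dependent variable is each subject's posterior-mean
connection strength (a two-step approach); first-level uncertainty is
honored in the parallel PEB variant with design
[mean, SRS, age, SRS x age, FD, site dummies] on the SRS-complete
subsample.  The linear mixed model has fixed effects
[intercept, SRS, age, SRS x age, FD] and a site random intercept, fitted by
REML profiled over the single variance ratio (1-D bounded search on
log rho); Wald tests use between-within denominator degrees of freedom
`N - p - (n_sites - 1)`.  statsmodels' MixedLM is the independent
cross-check in the test suite, not the implementation.  BH-FDR is applied
over the family of connections tested for the SRS x age term.  The
low/mid/high SRS stratification at mean +/- 1 SD (boundaries to mid,
SD with n-1 denominator) is presentation only.

## Synthetic cohorts

The generator emulates the study population: 166 ASD / 193 TD males over 8
sites; ages truncated-normal with ASD 17.6 (7.6) years in [7, 50] and TD
16.9 (6.6) in [6.5, 39.4]; SRS group-conditional (ASD 89.4 (32.4), TD 22.2
(18.1)) with ~39% missing (matching an SRS-complete subsample of 219/359);
mean FD normal (0.12, 0.06) truncated at 0.01, with the 0.34 mm exclusion
flag.  Per-subject couplings are baseline (bottom-up +0.15, top-down +0.10,
self log 0) plus covariate effects from a configurable table plus N(0,
0.05 Hz) subject noise, resampled until A is stable.  The default effect
table encodes the qualitative pattern the pipeline is designed to detect:
TD age slope +0.10/SD on every self-connection and -0.08 Hz/SD on every
bottom-up coupling, ASD slopes at 25% of TD's.  `make_confounded_sites`
scales per-site mean-age offsets (severity 1 spreads site means over
+/-6 years) to reproduce the age-site confounding situation.

BOLD is sampled from the same model the DCM assumes: spectrally shaped
neuronal noise, Euler-Maruyama integration at dt = tr/16 (eigenmode IIR
filtering for speed), frequency-domain hemodynamic filtering, downsampling
to TR, 60 s burn-in, and spectrally shaped observation noise whose
amplitude is set to a relative level (default 15% SD) inflated by motion,
`1 + 0.5 * FD`.  What the generator does **not** emulate: spatial structure,
scanner drift beyond polynomial trends, spike artifacts, nonlinear
hemodynamics, inter-site acquisition differences other than age
confounding.  Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not robustness
to real-fMRI model violation.

`sample_posterior_cohort` is a synthetic stand-in for the inversion stage:
first-level coupling posteriors drawn as N(truth, sd^2 I).  Group-level
calibration and confounding experiments use it so the hierarchical
machinery is exercised in isolation at desk-scale cost; the inversion
itself is validated separately (oracle, self-consistency and recovery
checks).

## Validation experiment sizes

The acceptance script (`scripts/acceptance.py`) uses: spectral oracle —
1–3-node systems, 65536 volumes, dt = tr/32, Welch with 128-sample
segments, median relative Frobenius error over the grid interior; parameter
recovery — 20 three-node subjects, 600 volumes; hierarchical recovery — 10
cohorts of N = 120 on a 4-node network (hub + 3 sensory nodes; 3 bottom-up
connections so "majority" is 2 of 3), 800 volumes/subject, a +0.1 Hz/SD
age-by-group interaction on bottom-up couplings (TD slope -0.133, ASD at
25%); null calibration and site confounding — 10 posterior-level cohorts of
N = 120 each; type-I error — 200 null replicates at N = 160 over 8 sites.
The 4-node, 800-volume choice is the smallest configuration in which the
interaction detection is limited by the effect, not by single-connection
sampling noise.

## Known limitations

- The variational posterior is a Laplace approximation at a mode of a
  ridge-shaped likelihood; its covariance understates subject-level error
  (observed ~7x on couplings), which the PEB layer absorbs into the
  between-subject component.  Group-level coverage is calibrated (null
  experiments), subject-level credible intervals are not.
- Spectral identifiability limits per-subject coupling accuracy to roughly
  +/-0.08 Hz at realistic record lengths regardless of further data; group
  effects rest on averaging across subjects.
- The two-pole hemodynamic surrogate and shared power-law noise are
  deliberate simplifications; they match the generator but not the full
  balloon model.
- Greedy BMA is a heuristic over an unenumerable model space; it is checked
  against exhaustive enumeration only on small spaces.
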