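# Methods

`riembci` implements an adaptive Riemannian classification pipeline for
multi-class mental-task EEG brain-computer interfaces, together with the
metrics used to study *user* learning across long-term training, and a
synthetic-data layer that makes every stage testable without recordings.

## The covariance-manifold model

Each 1 s EEG window is summarized by its spatial covariance matrix (SCM),
a channels × channels symmetric positive definite (SPD) matrix estimated
with the Ledoit–Wolf optimal linear shrinkage (guaranteeing positive
definiteness even when the window is shorter than the channel count).  SCMs
are analyzed on the SPD manifold under the affine-invariant metric

d(A, B) = ‖log(A^{-1/2} B A^{-1/2})‖_F = (Σ_l log² λ_l)^{1/2},

where λ_l are the generalized eigenvalues of (B, A).  The metric is
invariant under congruence transforms C ↦ W C Wᵀ for any invertible W —
the property the whole adaptation strategy rests on, because linear
mixing of sources, reference changes and gain drifts all act as
congruences.

The Karcher (Fréchet) mean of a set of SCMs is computed by the classical
fixed-point scheme: average the log-maps at the current estimate, exp-map
the average back, iterate until the tangent-gradient Frobenius norm falls
below `tol`.  Defaults: unit step, `tol = 1e-8`, `max_iter = 200`.  The
iteration converges linearly with a rate that worsens with set dispersion
(~0.8 per step on sets whose eigenvalue spread covers two orders of
magnitude), which is why the budget is 200 rather than the few dozen
iterations well-conditioned sets need.  Eigenvalues are clipped at 1e-12
(with a warning) inside all matrix functions; inputs asymmetric beyond
1e-6 relative are errors, below that they are silently symmetrized.

## Classification

* **MDM** — per-class Karcher means; a query gets the label of the nearest
  mean.  Ties break to the first class in declared order and are logged.
* **FGDA / FgMDM** — covariances are log-mapped at the global training
  mean and half-vectorized with √2 off-diagonal weights (so the Euclidean
  inner product equals the Frobenius one).  A multi-class Fisher
  discriminant with Ledoit–Wolf-regularized within-class scatter supplies
  ≤ (n_classes − 1) discriminant directions A; the geodesic filter is the
  orthogonal projector W = A(AᵀA)⁻¹Aᵀ applied to tangent vectors before
  mapping back to the manifold.  W is idempotent, so the filter is too.
  FgMDM = FGDA filtering followed by MDM on the filtered covariances.
* **Pseudo-probabilities** — distances to class means are converted by
  p_i = min_j d_j / d_i, P_i = p_i / Σ p_i, using *squared* distances as
  the scores.  With N classes the selected class's probability is at
  least 1/N (0.25 for four classes).
* **CSP + LDA baseline** — 2-class only: six spatial filters from the
  generalized eigendecomposition of the class covariances (three largest,
  three smallest eigenvalues), log-variance features, linear discriminant.
  The log-variance feature is the standard choice for this pipeline.

## Unsupervised adaptation

Non-stationarity is handled purely through congruences of the *inputs*;
classifier weights never change, so the feedback loop cannot destabilize:

1. **Recentering (rebias).**  C ↦ C̄^{-1/2} C C̄^{-1/2} moves a set's
   Karcher mean to the identity.  Online, the unseen test-set mean is
   tracked incrementally: C̄_{i+1} = geodesic(C̄_i, C_{i+1}; 1/(i+1)),
   initialized at the training mean with count 1.  Over a commuting
   stream this equals the running geometric mean exactly.  Prediction for
   epoch i happens *before* the update with epoch i (configurable), so an
   epoch never influences its own feedback; artifact-rejected epochs
   never update the state.
2. **Session-baseline projection.**  Each session records a ~2 min
   eyes-open resting baseline; the congruence by the inverse square root
   of the baseline's Karcher mean maps every session — training and test
   alike — toward a common reference before recentering.

A caveat worth stating precisely: when two sessions differ by a congruence
W and their baselines are shifted identically, the baseline projection
aligns them only up to the orthogonal matrix
P = (W B̄ Wᵀ)^{-1/2} W B̄^{1/2} (B̄ the baseline mean).  The projection is
exact when B̄ commutes with W — in particular for an isotropic baseline
and a symmetric positive shift, which is the synthetic generator's session
model.  The residual rotation is exactly what remains for the *user* to
adapt to in the user-learning simulation below.

## Command gating

A discrete command is emitted only after N_e consecutive epochs with the
same predicted label, each with pseudo-probability above P_c (defaults
N_e = 8, P_c = 0.3; one epoch every 1/8 s).  An epoch below the floor
breaks the streak entirely.  Two post-emission policies ship: `reset`
(default — the streak restarts, so a sustained task emits at most one
command per N_e epochs) and `sliding` (plain sliding window; overlapping
emissions possible).  The streaming implementation is verified against a
brute-force oracle that re-examines the last N_e epochs at every step.

## User-learning metrics

* **classDis** (classifier-independent distinctiveness): 2-class form
  d(C̄_a, C̄_b) / (½(σ_a + σ_b)); multi-class aggregate
  Σ_i d(C̄(c_i), C̄) / Σ_i σ_i.  σ is the *square root* of the Fréchet
  variance (a standard deviation), which keeps the ratio dimensionless
  and matches the metric's literature; the squared form is available via
  a flag for sensitivity checks.
* **TTA (test–train adaptation)**: landmarks are the per-class means plus
  the global mean.  TTA = 1/(N_c+1) · [Σ_i d(train_i, test_i)/σ_train,i +
  d(train, test)/σ_train], computed on covariances recentered the same way
  the online pipeline recenters them.  Lower TTA = the user's EEG matches
  the classifier's training distribution more closely.
* **Robust Fisher score** of band power (α 8–12, low-β 13–20, high-β
  21–30 Hz; Welch PSD, 0.5 s Hann segments, 50 % overlap — the spectral
  estimator is a package choice): FS = Σ_i (m_i − m_0)² / Σ_i mad_i²
  with class medians m_i and unscaled MADs (no 1.4826 factor), in linear
  power units.  The center m_0 defaults to the *mean* of the class
  medians (the classical Fisher-score center); a literal-sum variant is
  available behind a flag.  Per-run scores average FS over a channel
  subset (e.g. motor-area electrodes).
* **Chance level**: upper bound of the central (1−α) binomial confidence
  interval of accuracy under random classification, as an exact binomial
  quantile.  **Trend tests**: Pearson correlation of a per-run metric
  with run index, two-sided p-value.

## EOG artifact rejection

Three periocular channels are filtered 1–10 Hz (Butterworth order 4) and
combined into V = EOG1 − EOG3 and H = EOG2 − (EOG1 + EOG3)/2.  A window is
clean iff mean|V| < T_V **and** mean|H| < T_H (strict: equality rejects);
thresholds are T_S = mean(|S|) + 3·std(|S|) with the population (N)
standard deviation, estimated once on training data and frozen.  Because
mean + 3·std is a *peak* detector, thresholds must be estimated on
baseline-dominated (artifact-sparse) stretches; estimating them on
heavily contaminated data inflates them past the artifacts themselves.
EEG windows are additionally rejected when any band-passed sample exceeds
70 μV.  Rejection only — no ICA or regression correction.  The 70 μV test
is applied to EEG channels only (EOG channels are handled by the V/H
test); counts per rejection reason are logged and conserved.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (config, seed) and return their
ground truth.  Defaults mirror the study regime: 4 classes (left hand,
right hand, mental subtraction, rest), 512 Hz, 1 s windows with 93.75 %
overlap, 10 trials/class/run; 16 channels by default (a speed choice —
real montages went up to 46 + 3 EOG).

* **Class structure**: class means are exp-maps at the identity of
  mutually orthogonal diagonal tangent directions, so pairwise mean
  distances equal `class_mean_spread` (default 1.2) exactly.  Samples are
  exp-mapped symmetric Gaussian tangent noise (per-coordinate std
  `dispersion`, default 0.25), a Riemannian-Gaussian family whose Karcher
  mean is the generating mean — parameter-recovery tests are exact in
  expectation.
* **Session shifts** are congruences by W = exp(S), S symmetric with
  ‖S‖_F = `session_shift_magnitude` (default 5.0, chosen once so that a
  classifier trained before the shift loses well over 15 accuracy points
  after it).  The baseline reference is isotropic (κ·I), so baseline
  projection undoes these shifts exactly in expectation — by design, to
  make recovery measurable against a known truth.
* **Raw EEG**: band-limited (8–24 Hz) Gaussian noise, empirically
  whitened per segment and mixed by the square root of the trial's class
  covariance, so segment sample covariances match the target exactly;
  ~10 μV RMS; a resting baseline segment precedes the trials.  **EOG**:
  baseline noise plus Gaussian-bump blink templates (opposite-sign
  deflections on EOG1/EOG3, ~150 μV) and EOG2-dominant saccades at
  Poisson times, with ground-truth intervals.
* **User adaptation**: the simulated user starts with a global congruence
  shift W = exp(G), G a random *general* matrix — the rotational part of
  G is precisely what recentering and baseline projection cannot remove.
  On run r the residual shift is exp((1 − t_r)·G), t_r = min(1, r·rate),
  reaching the training configuration as t → 1.  Because every run's
  class-mean configuration stays congruent to the training one, class
  distinctiveness is constant by construction, while accuracy rises and
  TTA falls — the dissociation of interest.  A per-class geodesic
  interpolation would *not* keep classDis constant, which is why the
  decaying-congruence path was chosen.

What passing tests on this data do **not** show: robustness to
non-congruence distortions (per-channel nonlinearities, electrode pops,
genuinely new sources appearing mid-session), realistic EEG spectra
(1/f background, line noise), or realistic baseline anisotropy.  In
particular, because the synthetic session shift is exactly removable by
the baseline projection, the recovery experiment measures the chain's
correctness, not its limits on real data.

## Numerical and design choices

* Epoching: windows start 1.25 s after the cue, 1 s long, 1/16 s shift,
  over a default 4 s of post-offset trial data (configurable; 49 windows
  per trial at the defaults).
* Zero-phase (forward–backward) Butterworth filtering offline; a causal
  single-pass mode exists for online simulation.
* Rebias count resets at run boundaries by default (persistence across
  runs is configurable via the returned state).
* Degenerate inputs: zero within-class dispersion makes classDis +∞ (with
  a warning); zero training dispersion makes TTA an error naming the
  class; all-zero MADs make the Fisher score +∞; constant trend inputs
  return NaN correlations with a warning.
* Experiment problem sizes (the acceptance script and tests): 16-channel,
  4-class sets with 100 training epochs/class, 50 test epochs/class, 12
  simulated runs, 180 s EOG stretches, 10⁴-step gate streams — sizes at
  which every statistic reported is stable while the whole suite runs in
  well under a minute of compute per experiment.

## Known limitations

* FGDA assumes the discriminant subspace is well-estimated from the
  tangent vectors at the global mean; with very small training sets the
  Ledoit–Wolf regularization keeps it defined but not necessarily good.
* The incremental rebias weights all epochs equally (1/(i+1) schedule); a
  heavily class-imbalanced stream biases the mean toward the dominant
  class.  The stream predictor logs a warning when the predicted-label
  distribution is highly skewed, but applies no correction.
* The session projector assumes the baseline reflects the same global
  transform as the task data; a baseline recorded under different
  conditions (eyes closed, different impedances) would misalign sessions.
* EDF/GDF reading requires the optional `mne` dependency; the tabular
  CSV fixture format is the fully supported text path.
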