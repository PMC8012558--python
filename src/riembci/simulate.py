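"""Synthetic EEG and covariance generators with known ground truth.

The generators emulate the statistical regime of a multi-session 4-class
mental-task BCI recording: class-conditional spatial covariance structure
(a Riemannian-Gaussian model whose Karcher mean is the generating class
mean), within-session dispersion, between-session global covariance shifts
applied as congruence transforms, band-limited oscillatory EEG colored by
the class covariances, and blink/saccade EOG deflections.  Every generator
is a pure function of (config, seed) and returns its ground truth alongside
the data, so each pipeline stage can be tested against an oracle without any
recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.linalg

from . import geometry as geo
from .geometry import SPDSet
from .preprocessing import RawRecording

__all__ = [
    "SimConfig",
    "sample_spd_class_set",
    "apply_session_shift",
    "synthesize_recording",
    "synthesize_eog",
    "simulate_user_adaptation",
]

#: Default class labels, in fixed order (affects only tie-breaks and layout).
CLASS_NAMES = ("LEFT_HAND", "RIGHT_HAND", "MENTAL_SUBTRACTION", "REST")


@dataclass
class SimConfig:
    """Study-regime defaults: 4 classes, 512 Hz, 1 s windows, 10 trials/class/run.

    ``class_mean_spread`` is the pairwise Riemannian distance between class
    means; ``dispersion`` the per-coordinate tangent-space noise std;
    ``session_shift_magnitude`` the norm of the log of the (symmetric
    positive) between-session congruence matrix, calibrated so that a
    classifier trained before the shift loses substantial accuracy after it.
    """

    n_channels: int = 16
    n_classes: int = 4
    class_mean_spread: float = 1.2
    dispersion: float = 0.25
    n_epochs_per_class: int = 100
    session_shift_magnitude: float = 5.0
    fs: float = 512.0
    n_trials_per_class: int = 10
    seed: int = 0
    eog_blink_rate: float = 10.0  # events / minute
    eog_amplitude: float = 150.0  # μV
    baseline_scale: float = 1.0  # eyes-open baseline reference = scale · I
    baseline_dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.n_channels < self.n_classes:
            raise ValueError("need n_channels >= n_classes to place orthogonal class means")
        if min(self.n_channels, self.n_classes, self.n_epochs_per_class) < 1:
            raise ValueError("counts must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")


def _rng(cfg_or_seed) -> np.random.Generator:
    seed = cfg_or_seed.seed if isinstance(cfg_or_seed, SimConfig) else cfg_or_seed
    return np.random.default_rng(seed)


def _class_means(cfg: SimConfig) -> np.ndarray:
    """Class means at equal pairwise Riemannian distance ``class_mean_spread``.

    Means are exp-maps at the identity of mutually orthogonal diagonal
    tangent directions of norm spread/√2; being commuting, their pairwise
    distances equal the tangent distances exactly.
    """
    s = cfg.class_mean_spread / np.sqrt(2.0)
    means = []
    for k in range(cfg.n_classes):
        d = np.zeros(cfg.n_channels)
        d[k] = s
        means.append(np.diag(np.exp(d)))
    return np.array(means)


def _sample_tangent_noise(rng: np.random.Generator, n: int, dim: int, sigma: float) -> np.ndarray:
    """Symmetric Gaussian tangent noise: N(0, σ²) diagonals, N(0, σ²/2) off-diagonals.

    Matches the √2-weighted vectorization so each tangent coordinate has std σ.
    """
    diag = rng.normal(0.0, sigma, size=(n, dim))
    off = rng.normal(0.0, sigma / np.sqrt(2.0), size=(n, dim, dim))
    off = np.triu(off, 1)
    sym = off + np.swapaxes(off, -1, -2)
    sym[:, np.arange(dim), np.arange(dim)] = diag
    return sym


def _sample_around(
    rng: np.random.Generator, mean: np.ndarray, n: int, sigma: float
) -> np.ndarray:
    """Riemannian-Gaussian samples around ``mean`` (its Karcher mean in expectation)."""
    dim = mean.shape[0]
    if sigma == 0:
        return np.repeat(mean[None], n, axis=0)
    noise = _sample_tangent_noise(rng, n, dim, sigma)
    sm, ism = geo.sqrtm(mean), geo.invsqrtm(mean)
    return sm @ geo.expm(noise) @ sm


def sample_spd_class_set(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[SPDSet, np.ndarray]:
    """Labeled covariance samples for each class, plus the true class means.

    Samples are exp-mapped symmetric Gaussian tangent noise at each class
    mean, so the empirical Karcher mean of each class converges to the
    generating mean.
    """
    rng = rng or _rng(cfg)
    means = _class_means(cfg)
    names = [
        CLASS_NAMES[k] if cfg.n_classes <= len(CLASS_NAMES) else f"CLASS_{k}"
        for k in range(cfg.n_classes)
    ]
    mats, labels = [], []
    for k in range(cfg.n_classes):
        mats.append(_sample_around(rng, means[k], cfg.n_epochs_per_class, cfg.dispersion))
        labels += [names[k]] * cfg.n_epochs_per_class
    return SPDSet(np.concatenate(mats), labels=np.array(labels)), means


def apply_session_shift(
    covs: SPDSet, magnitude: float, seed: int = 0
) -> Tuple[SPDSet, np.ndarray]:
    """Congruence-transform every sample by a random session-shift matrix.

    The shift is W = exp(S) with S a random symmetric matrix scaled to
    Frobenius norm ``magnitude`` — an invertible matrix whose polar-positive
    part has log-norm exactly ``magnitude`` (no orthogonal component).
    Returns the shifted set and W for oracle tests.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be nonnegative")
    dim = covs.dim
    if magnitude == 0:
        return SPDSet(covs.mats.copy(), covs.labels, covs.session_ids), np.eye(dim)
    rng = _rng(seed)
    s = _sample_tangent_noise(rng, 1, dim, 1.0)[0]
    s *= magnitude / np.linalg.norm(s)
    w = geo.expm(s)
    return SPDSet(geo.congruence(covs.mats, w), covs.labels, covs.session_ids), w


def _colored_noise(
    rng: np.random.Generator, cov: np.ndarray, n_samples: int, fs: float
) -> np.ndarray:
    """Band-limited (8–24 Hz dominated) noise with spatial covariance ``cov``.

    White noise is band-passed, empirically whitened over the segment, then
    mixed by the matrix square root of the target covariance — the segment's
    sample covariance matches ``cov`` exactly by construction.
    """
    from .preprocessing import bandpass_array

    dim = cov.shape[0]
    pad = int(fs)  # discard filter edge effects
    white = rng.standard_normal((n_samples + 2 * pad, dim))
    shaped = bandpass_array(white, fs, 8.0, 24.0, order=4)[pad:-pad]
    shaped = shaped - shaped.mean(0)
    shaped = shaped @ geo.invsqrtm(np.cov(shaped.T)).T
    return shaped @ geo.sqrtm(cov).T


def synthesize_recording(
    cfg: SimConfig,
    class_covs: Optional[np.ndarray] = None,
    baseline_duration: float = 10.0,
    trial_duration: float = 6.0,
    inter_trial: float = 1.0,
    amplitude_uv: float = 10.0,
) -> Tuple[RawRecording, Dict]:
    """A cued-trial EEG recording colored by per-class covariances.

    Layout: an eyes-open resting baseline segment, then for each trial an
    inter-trial rest gap and ``trial_duration`` seconds of activity drawn
    from the trial's class covariance (scaled to ``amplitude_uv`` μV RMS).
    Cue events mark trial onsets.  Ground truth (class covariances in μV²,
    trial labels, baseline extent) is returned alongside.
    """
    rng = _rng(cfg)
    if class_covs is None:
        class_covs = _class_means(cfg)
    scale = amplitude_uv**2
    covs_uv = class_covs * scale
    base_cov = cfg.baseline_scale * scale * np.eye(cfg.n_channels)

    fs = cfg.fs
    order = np.repeat(np.arange(cfg.n_classes), cfg.n_trials_per_class)
    rng.shuffle(order)

    segments = [_colored_noise(rng, base_cov, int(baseline_duration * fs), fs)]
    events: List[Tuple[float, str]] = []
    t = baseline_duration
    for k in order:
        segments.append(_colored_noise(rng, base_cov, int(inter_trial * fs), fs))
        t += inter_trial
        events.append((t, CLASS_NAMES[k]))
        segments.append(_colored_noise(rng, covs_uv[k], int(trial_duration * fs), fs))
        t += trial_duration
    data = np.concatenate(segments, axis=0)
    names = [f"C{i+1}" for i in range(cfg.n_channels)]
    rec = RawRecording(data=data, fs=fs, channel_names=names, events=events)
    truth = {
        "class_covs_uv2": covs_uv,
        "baseline_duration": baseline_duration,
        "trial_duration": trial_duration,
        "trial_labels": [CLASS_NAMES[k] for k in order],
    }
    return rec, truth


def synthesize_eog(
    duration: float, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[np.ndarray, List[Tuple[float, float]]]:
    """Three EOG channels with injected blinks and saccades.

    Blinks are synchronized opposite-sign deflections on EOG1/EOG3 (peaking
    in the vertical derivation V); saccades are EOG2-dominant steps (peaking
    in H).  Events occur at Poisson times at ``eog_blink_rate`` per minute
    (split between blinks and saccades).  Returns (samples × 3) signals and
    the ground-truth artifact intervals in seconds.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = rng or _rng(cfg)
    n = int(duration * cfg.fs)
    t = np.arange(n) / cfg.fs
    eog = rng.normal(0.0, 3.0, size=(n, 3))  # baseline ocular noise, μV

    intervals: List[Tuple[float, float]] = []
    rate_hz = cfg.eog_blink_rate / 60.0
    n_events = rng.poisson(rate_hz * duration)
    times = np.sort(rng.uniform(0.3, max(duration - 0.5, 0.31), size=n_events))
    for t0 in times:
        width = 0.15  # s
        template = np.exp(-0.5 * ((t - t0) / (width / 2)) ** 2)
        if rng.uniform() < 0.7:  # blink → vertical derivation peak
            eog[:, 0] += cfg.eog_amplitude * template
            eog[:, 2] -= 0.8 * cfg.eog_amplitude * template
        else:  # saccade → horizontal derivation peak
            eog[:, 1] += 0.8 * cfg.eog_amplitude * np.sign(rng.uniform() - 0.5) * template
        intervals.append((max(t0 - 2 * width, 0.0), min(t0 + 2 * width, duration)))
    return eog, intervals


def simulate_user_adaptation(
    cfg: SimConfig,
    n_runs: int = 12,
    adaptation_rate: float = 1.0 / 12.0,
) -> Tuple[SPDSet, List[SPDSet], Dict]:
    """Per-run covariance sets emulating a user adapting to the classifier.

    The training set is drawn around the reference class means.  The user
    starts with a global congruence shift W = exp(G) of magnitude
    ``session_shift_magnitude``, where G is a random *general* matrix — the
    shift carries both a positive-definite stretching and a rotational
    component, since a rotation is the part of a real inter-session shift
    that mean-recentering cannot remove.  On run r the residual shift is
    W_r = exp((1 − t_r) G) with t_r = min(1, r · adaptation_rate), so the
    run-r class means move from the shifted configuration back to the
    training landmarks while remaining congruent to them — class
    distinctiveness is constant by construction, while accuracy rises and
    test–train adaptation falls as the user's data approach the training
    distribution.
    """
    if not 0 <= adaptation_rate <= 1:
        raise ValueError("adaptation_rate must lie in [0, 1]")
    rng = _rng(cfg)
    means = _class_means(cfg)
    train_mats, train_labels = [], []
    for k in range(cfg.n_classes):
        train_mats.append(_sample_around(rng, means[k], cfg.n_epochs_per_class, cfg.dispersion))
        train_labels += [CLASS_NAMES[k]] * cfg.n_epochs_per_class
    train = SPDSet(np.concatenate(train_mats), labels=np.array(train_labels))

    g = rng.standard_normal((cfg.n_channels, cfg.n_channels))
    if np.linalg.norm(g) > 0:
        g *= cfg.session_shift_magnitude / np.linalg.norm(g)

    runs: List[SPDSet] = []
    fractions = []
    for r in range(1, n_runs + 1):
        t_r = min(1.0, r * adaptation_rate)
        fractions.append(t_r)
        w_r = scipy.linalg.expm((1.0 - t_r) * g)
        run_means = geo.congruence(means, w_r)
        mats, labels = [], []
        for k in range(cfg.n_classes):
            mats.append(_sample_around(rng, run_means[k], cfg.n_epochs_per_class, cfg.dispersion))
            labels += [CLASS_NAMES[k]] * cfg.n_epochs_per_class
        runs.append(SPDSet(np.concatenate(mats), labels=np.array(labels)))
    truth = {"class_means": means, "shift_log": g, "adaptation_fractions": fractions}
    return train, runs, truth
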