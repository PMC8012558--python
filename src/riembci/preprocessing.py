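"""EEG preprocessing: band-pass filtering, epoching, artifact rejection and
shrinkage covariance estimation.

The pipeline mirrors a cue-based mental-task BCI front-end: EEG is band-pass
filtered (8–24 Hz Butterworth, order 4, zero-phase by default), segmented into
overlapping windows after each instruction cue, screened for high-amplitude
artifacts (|x| > 70 μV on the filtered EEG) and for ocular artifacts via three
EOG channels combined into vertical and horizontal derivations, and each
surviving window is summarized by its Ledoit–Wolf shrinkage spatial covariance
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.signal
from sklearn.covariance import LedoitWolf

from .geometry import SPDSet

__all__ = [
    "RawRecording",
    "EpochWindow",
    "EOGThresholds",
    "PreprocessingConfig",
    "bandpass",
    "bandpass_array",
    "epoch",
    "amplitude_reject",
    "eog_derivations",
    "estimate_eog_thresholds",
    "eog_reject",
    "shrinkage_covariance",
    "preprocess_recording",
]


@dataclass
class RawRecording:
    """A raw multichannel recording (samples × channels, μV)."""

    data: np.ndarray
    fs: float
    channel_names: List[str]
    events: List[Tuple[float, str]] = field(default_factory=list)
    eog_channels: Optional[List[str]] = None
    session_id: str = "S01"
    run_id: str = "R01"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match the number of data columns")
        duration = self.data.shape[0] / self.fs
        for onset, _ in self.events:
            if not 0 <= onset <= duration:
                raise ValueError(f"event onset {onset} s outside recording of {duration:.2f} s")
        if self.eog_channels is not None:
            missing = [c for c in self.eog_channels if c not in self.channel_names]
            if missing:
                raise ValueError(f"EOG channels not present in recording: {missing}")

    @property
    def duration(self) -> float:
        return self.data.shape[0] / self.fs

    @property
    def eeg_channel_names(self) -> List[str]:
        eog = set(self.eog_channels or [])
        return [c for c in self.channel_names if c not in eog]

    def channel_data(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.channel_names.index(n) for n in names]
        return self.data[:, idx]


@dataclass
class EpochWindow:
    """One analysis window: channels × time (μV), with its cue label."""

    data: np.ndarray
    fs: float
    onset: float
    label: str
    clean: bool = True

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EOGThresholds:
    """Rejection thresholds for the vertical / horizontal EOG derivations."""

    t_v: float
    t_h: float


@dataclass
class PreprocessingConfig:
    """Defaults follow the online pipeline this package reproduces."""

    eeg_band: Tuple[float, float] = (8.0, 24.0)
    eog_band: Tuple[float, float] = (1.0, 10.0)
    filter_order: int = 4
    zero_phase: bool = True
    window_s: float = 1.0
    shift_s: float = 1.0 / 16.0
    start_offset_s: float = 1.25
    trial_duration_s: float = 4.0
    amplitude_threshold_uv: float = 70.0
    eog_thresholds: Optional[EOGThresholds] = None


def bandpass_array(
    data: np.ndarray,
    fs: float,
    low: float,
    high: float,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth band-pass along axis 0 (samples × channels).

    Zero-phase (forward–backward) filtering by default for offline
    reproducibility; ``zero_phase=False`` gives the causal single-pass
    variant used when simulating online operation.
    """
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {nyq}")
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        return scipy.signal.sosfiltfilt(sos, data, axis=0)
    return scipy.signal.sosfilt(sos, data, axis=0)


def bandpass(
    rec: RawRecording,
    low: float = 8.0,
    high: float = 24.0,
    order: int = 4,
    zero_phase: bool = True,
    channels: Optional[Sequence[str]] = None,
) -> RawRecording:
    """Return a copy of ``rec`` with the selected channels band-pass filtered."""
    data = rec.data.copy()
    names = rec.channel_names if channels is None else list(channels)
    idx = [rec.channel_names.index(n) for n in names]
    data[:, idx] = bandpass_array(rec.data[:, idx], rec.fs, low, high, order, zero_phase)
    return replace(rec, data=data)


def epoch(
    rec: RawRecording,
    start_offset: float = 1.25,
    window: float = 1.0,
    shift: float = 1.0 / 16.0,
    trial_duration: float = 4.0,
    channels: Optional[Sequence[str]] = None,
) -> Tuple[List[EpochWindow], int]:
    """Cut overlapping windows out of each cued trial.

    For each event, windows of length ``window`` start at
    ``onset + start_offset`` and advance by ``shift`` for as long as they fit
    within ``trial_duration`` seconds of post-offset data.  Windows that would
    extend past the end of the recording are dropped and counted.

    Returns the windows and the number dropped at the recording boundary.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not 0 < shift <= window:
        raise ValueError("shift must satisfy 0 < shift <= window")
    names = rec.eeg_channel_names if channels is None else list(channels)
    data = rec.channel_data(names)
    n_samples = data.shape[0]
    t_win = int(round(window * rec.fs))
    windows: List[EpochWindow] = []
    n_dropped = 0
    for onset, label in rec.events:
        t0 = onset + start_offset
        k = 0
        while k * shift + window <= trial_duration + 1e-9:
            start = t0 + k * shift
            i0 = int(round(start * rec.fs))
            k += 1
            if i0 + t_win > n_samples:
                n_dropped += 1
                continue
            windows.append(
                EpochWindow(data=data[i0 : i0 + t_win].T, fs=rec.fs, onset=start, label=label)
            )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} windows extending past the recording end")
    return windows, n_dropped


def amplitude_reject(window_data: np.ndarray, threshold_uv: float = 70.0) -> bool:
    """True (reject) iff any sample's absolute amplitude exceeds the threshold."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    return bool(np.max(np.abs(window_data)) > threshold_uv)


def eog_derivations(
    eog1: np.ndarray, eog2: np.ndarray, eog3: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Vertical and horizontal EOG derivations from the three periocular channels.

    V = EOG1 − EOG3 (electrodes above/below the eye);
    H = EOG2 − (EOG1 + EOG3)/2 (electrode on the horizontal line).
    """
    eog1, eog2, eog3 = (np.asarray(x, float) for x in (eog1, eog2, eog3))
    if not (len(eog1) == len(eog2) == len(eog3)):
        raise ValueError("EOG channels must have equal lengths")
    v = eog1 - eog3
    h = eog2 - 0.5 * (eog1 + eog3)
    return v, h


def estimate_eog_thresholds(v: np.ndarray, h: np.ndarray) -> EOGThresholds:
    """Thresholds T_S = mean(|S|) + 3·std(|S|) for S ∈ {V, H}.

    Estimated on (already 1–10 Hz filtered) training EOG; the dispersion is
    the population (N-denominator) standard deviation of |S|.
    """
    v, h = np.asarray(v, float), np.asarray(h, float)
    if v.size == 0 or h.size == 0:
        raise ValueError("cannot estimate thresholds from empty signals")

    def _th(s: np.ndarray) -> float:
        a = np.abs(s)
        return float(a.mean() + 3.0 * a.std())

    return EOGThresholds(t_v=_th(v), t_h=_th(h))


def eog_reject(v_seg: np.ndarray, h_seg: np.ndarray, th: EOGThresholds) -> bool:
    """Ocular-artifact decision for one window.

    A window is clean iff mean(|V_t|) < T_V AND mean(|H_t|) < T_H (strict
    inequalities — a mean exactly at threshold rejects).  Returns the
    *reject* decision.
    """
    clean = (np.mean(np.abs(v_seg)) < th.t_v) and (np.mean(np.abs(h_seg)) < th.t_h)
    return not clean


def shrinkage_covariance(window_data: np.ndarray, shrinkage: Optional[float] = None) -> np.ndarray:
    """Ledoit–Wolf shrinkage spatial covariance of a channels × time window.

    Shrinkage toward a scaled identity keeps the estimate SPD even when the
    window is shorter than the channel count.  Constant-channel degenerate
    windows are handled by the shrinkage itself (warning emitted).

    ``shrinkage`` forces a fixed intensity in [0, 1] instead of the
    Ledoit–Wolf optimum (0 reproduces the plain sample covariance).
    """
    x = np.asarray(window_data, float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("window must be channels × time with at least 2 samples")
    if np.any(np.ptp(x, axis=1) == 0):
        warnings.warn("window contains a constant channel; shrinkage keeps the estimate SPD")
    if shrinkage is None:
        cov = LedoitWolf(assume_centered=False).fit(x.T).covariance_
    else:
        if not 0 <= shrinkage <= 1:
            raise ValueError("shrinkage must lie in [0, 1]")
        emp = np.cov(x, bias=True)
        mu = np.trace(emp) / emp.shape[0]
        cov = (1 - shrinkage) * emp + shrinkage * mu * np.eye(emp.shape[0])
    # guard: shrinkage target is λ·μ·I with μ>0, so this only trips on all-zero input
    w = np.linalg.eigvalsh(cov)
    if w.min() <= 0:
        cov = cov + (abs(w.min()) + 1e-10) * np.eye(cov.shape[0])
    return 0.5 * (cov + cov.T)


def preprocess_recording(
    rec: RawRecording,
    config: Optional[PreprocessingConfig] = None,
    eog_thresholds: Optional[EOGThresholds] = None,
) -> Tuple[SPDSet, List[EpochWindow], Dict[str, int]]:
    """Full front-end: filter → epoch → reject → shrinkage covariances.

    EOG thresholds can be passed in (frozen from training data); otherwise,
    when the recording has EOG channels, they are estimated from this
    recording's filtered derivations.  Returns the covariance set of clean
    windows (labels and session ids attached), all windows with their
    ``clean`` flags, and a manifest of counts per rejection reason satisfying
    ``kept + rejected_amplitude + rejected_eog + dropped_boundary = generated``.
    """
    cfg = config or PreprocessingConfig()
    eeg = bandpass(
        rec, *cfg.eeg_band, order=cfg.filter_order, zero_phase=cfg.zero_phase,
        channels=rec.eeg_channel_names,
    )
    windows, n_dropped = epoch(
        eeg,
        start_offset=cfg.start_offset_s,
        window=cfg.window_s,
        shift=cfg.shift_s,
        trial_duration=cfg.trial_duration_s,
    )
    n_generated = len(windows) + n_dropped

    v = h = None
    th = eog_thresholds or cfg.eog_thresholds
    if rec.eog_channels:
        eog_raw = rec.channel_data(rec.eog_channels)
        eog_filt = bandpass_array(
            eog_raw, rec.fs, *cfg.eog_band, order=cfg.filter_order, zero_phase=cfg.zero_phase
        )
        v, h = eog_derivations(eog_filt[:, 0], eog_filt[:, 1], eog_filt[:, 2])
        if th is None:
            th = estimate_eog_thresholds(v, h)

    kept: List[EpochWindow] = []
    n_amp = n_eog = 0
    for w in windows:
        if amplitude_reject(w.data, cfg.amplitude_threshold_uv):
            w.clean = False
            n_amp += 1
            continue
        if v is not None and th is not None:
            i0 = int(round(w.onset * rec.fs))
            seg = slice(i0, i0 + w.n_samples)
            if eog_reject(v[seg], h[seg], th):
                w.clean = False
                n_eog += 1
                continue
        kept.append(w)

    covs = SPDSet(
        mats=np.array([shrinkage_covariance(w.data) for w in kept]).reshape(
            len(kept), len(rec.eeg_channel_names), len(rec.eeg_channel_names)
        ),
        labels=np.array([w.label for w in kept]) if kept else np.array([]),
        session_ids=np.array([rec.session_id] * len(kept)) if kept else np.array([]),
    )
    manifest = {
        "generated": n_generated,
        "kept": len(kept),
        "rejected_amplitude": n_amp,
        "rejected_eog": n_eog,
        "dropped_boundary": n_dropped,
    }
    return covs, windows, manifest
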