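"""User-learning and discriminability metrics for mental-task BCI data.

* **classDis** — classifier-independent distinctiveness of the EEG classes:
  Riemannian distance between class means normalized by within-class
  dispersion (2-class and multi-class aggregate forms).
* **TTA (test–train adaptation)** — normalized Riemannian distances between
  training-set and test-set landmarks (per-class means plus the global
  mean); decreasing TTA over runs means the user's EEG increasingly matches
  the distribution the classifier was trained on.
* **Robust Fisher score** — band-power class discriminability using class
  medians and median absolute deviations.
* Chance-level upper confidence limits and Pearson run-index trend tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from . import geometry as geo
from .geometry import SPDSet

__all__ = [
    "LandmarkSet",
    "DEFAULT_BANDS",
    "class_dis_2",
    "class_dis_multi",
    "compute_landmarks",
    "tta",
    "band_power",
    "robust_fisher_score",
    "chance_level_upper",
    "learning_trend",
]

#: Frequency bands used in the neurophysiological analyses (Hz).
DEFAULT_BANDS: Dict[str, Tuple[float, float]] = {
    "alpha": (8.0, 12.0),
    "low_beta": (13.0, 20.0),
    "high_beta": (21.0, 30.0),
}


@dataclass
class LandmarkSet:
    """Per-class and global Karcher means with their Fréchet dispersions."""

    class_ids: np.ndarray
    class_means: np.ndarray  # (n_classes, d, d)
    class_stds: np.ndarray  # (n_classes,)
    global_mean: np.ndarray  # (d, d)
    global_std: float


def _dispersion(mats: np.ndarray, mean: np.ndarray, squared: bool = False) -> float:
    var = geo.riemannian_variance(mats, mean)
    return var if squared else float(np.sqrt(var))


def class_dis_2(covs_a: SPDSet, covs_b: SPDSet, squared_dispersion: bool = False) -> float:
    """Two-class distinctiveness: d(mean_a, mean_b) / (½(σ_a + σ_b)).

    σ defaults to the square root of the Fréchet variance (a standard
    deviation, keeping the ratio dimensionless); ``squared_dispersion=True``
    uses the variance itself.
    """
    if len(covs_a) == 0 or len(covs_b) == 0:
        raise ValueError("both covariance sets must be non-empty")
    mean_a, mean_b = geo.karcher_mean(covs_a.mats), geo.karcher_mean(covs_b.mats)
    num = geo.riemannian_distance(mean_a, mean_b)
    sig = 0.5 * (
        _dispersion(covs_a.mats, mean_a, squared_dispersion)
        + _dispersion(covs_b.mats, mean_b, squared_dispersion)
    )
    if sig < 1e-12:  # numerically zero dispersion
        warnings.warn("zero within-class dispersion; classDis is undefined (+inf)")
        return float("inf")
    return num / sig


def class_dis_multi(covs: SPDSet, squared_dispersion: bool = False) -> float:
    """Multi-class distinctiveness, aggregated over classes.

    Σ_i d(C̄(c_i), C̄) / Σ_i σ_{c_i}: distances of each class mean from the
    grand mean, normalized by the summed within-class dispersions.
    """
    lm = compute_landmarks(covs, squared_dispersion=squared_dispersion)
    num = sum(
        geo.riemannian_distance(m, lm.global_mean) for m in lm.class_means
    )
    denom = float(np.sum(lm.class_stds))
    if denom < 1e-12:  # numerically zero dispersion
        warnings.warn("zero total dispersion; classDis is undefined (+inf)")
        return float("inf")
    return num / denom


def compute_landmarks(covs: SPDSet, squared_dispersion: bool = False) -> LandmarkSet:
    """Per-class and global Karcher means and dispersions of a labeled set.

    For test–train adaptation, the inputs should already be recentered the
    same way the online pipeline recenters them (session-baseline projection
    then rebias).
    """
    if covs.labels is None:
        raise ValueError("landmarks require labeled covariances")
    classes = covs.classes()
    means, stds = [], []
    for c in classes:
        mats = covs.mats[covs.labels == c]
        m = geo.karcher_mean(mats)
        means.append(m)
        stds.append(_dispersion(mats, m, squared_dispersion))
    gmean = geo.karcher_mean(covs.mats)
    return LandmarkSet(
        class_ids=classes,
        class_means=np.array(means),
        class_stds=np.array(stds),
        global_mean=gmean,
        global_std=_dispersion(covs.mats, gmean, squared_dispersion),
    )


def tta(train: LandmarkSet, test: LandmarkSet) -> float:
    """Test–train adaptation: average normalized landmark displacement.

    ``TTA = 1/(N_c+1) [ Σ_i d(C̄train(c_i), C̄test(c_i))/σtrain(c_i)
    + d(C̄train, C̄test)/σtrain ]`` — zero iff every test landmark coincides
    with its training counterpart; lower values mean the test distribution
    sits closer to the training one.
    """
    if not np.array_equal(train.class_ids, test.class_ids):
        raise ValueError("train and test landmark sets must share the same classes")
    for c, s in zip(train.class_ids, train.class_stds):
        if s == 0:
            raise ValueError(f"training dispersion of class {c!r} is zero")
    if train.global_std == 0:
        raise ValueError("global training dispersion is zero")
    terms = [
        geo.riemannian_distance(mtr, mte) / s
        for mtr, mte, s in zip(train.class_means, test.class_means, train.class_stds)
    ]
    terms.append(geo.riemannian_distance(train.global_mean, test.global_mean) / train.global_std)
    return float(np.sum(terms) / (len(train.class_ids) + 1))


def band_power(
    epochs: np.ndarray,
    fs: float,
    bands: Optional[Dict[str, Tuple[float, float]]] = None,
    labels: Optional[Sequence] = None,
    run_ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-epoch, per-channel mean power spectral density within each band.

    Welch estimate (0.5 s Hann segments, 50% overlap).  Returns a long-form
    DataFrame with columns epoch, channel, band, power (+ label, run_id when
    given).

    ``epochs``: (n_epochs, n_channels, n_times), μV.
    """
    bands = bands or DEFAULT_BANDS
    nyq = fs / 2.0
    for name, (lo, hi) in bands.items():
        if not 0 <= lo < hi < nyq:
            raise ValueError(f"band {name} ({lo}-{hi} Hz) outside Nyquist range (0, {nyq})")
    epochs = np.asarray(epochs, float)
    nperseg = min(int(fs // 2), epochs.shape[2])
    freqs, psd = scipy.signal.welch(
        epochs, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=2
    )
    rows = []
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        power = psd[:, :, sel].mean(axis=2)  # (n_epochs, n_channels)
        for e in range(epochs.shape[0]):
            for ch in range(epochs.shape[1]):
                rows.append(
                    {
                        "epoch": e,
                        "channel": ch,
                        "band": name,
                        "power": power[e, ch],
                        "label": None if labels is None else labels[e],
                        "run_id": None if run_ids is None else run_ids[e],
                    }
                )
    return pd.DataFrame(rows)


def robust_fisher_score(
    table: pd.DataFrame,
    band: str,
    channels: Optional[Iterable[int]] = None,
    m0: str = "mean",
) -> pd.Series:
    """Per-run robust Fisher score of band power, averaged over channels.

    For each run and channel, FS = Σ_i (m_i − m_0)² / Σ_i mad_i² with m_i the
    class median and mad_i the class median absolute deviation of power in
    the requested band; the per-run score is the mean FS over the channel
    subset (e.g. the motor-area electrodes).  ``m0`` is the central value of
    the class medians: "mean" (default, the classical Fisher-score center) or
    "sum" (the literal printed form).
    """
    if m0 not in ("mean", "sum"):
        raise ValueError("m0 must be 'mean' or 'sum'")
    df = table[table["band"] == band]
    if channels is not None:
        df = df[df["channel"].isin(list(channels))]
    scores: Dict = {}
    for run, run_df in df.groupby("run_id"):
        if run_df["label"].nunique() < 2:
            raise ValueError(f"run {run!r} has fewer than 2 classes")
        per_channel = []
        for _, ch_df in run_df.groupby("channel"):
            med = ch_df.groupby("label")["power"].median()
            mad = ch_df.groupby("label")["power"].apply(
                lambda x: float(np.median(np.abs(x - np.median(x))))
            )
            center = med.mean() if m0 == "mean" else med.sum()
            denom = float((mad**2).sum())
            num = float(((med - center) ** 2).sum())
            if denom == 0:
                warnings.warn("all class MADs are zero; Fisher score is +inf")
                per_channel.append(float("inf") if num > 0 else 0.0)
            else:
                per_channel.append(num / denom)
        scores[run] = float(np.mean(per_channel))
    return pd.Series(scores).sort_index()


def chance_level_upper(
    n_trials_per_class: int, n_classes: int, alpha: float = 0.05
) -> float:
    """Upper confidence limit (%) of the chance-level classification accuracy.

    Upper bound of the central (1−α) binomial confidence interval for the
    accuracy of random classification with success probability 1/n_classes
    over n_classes × n_trials_per_class trials.
    """
    if n_trials_per_class < 1:
        raise ValueError("n_trials_per_class must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n = n_trials_per_class * n_classes
    k = scipy.stats.binom.ppf(1 - alpha / 2, n, 1.0 / n_classes)
    return float(100.0 * k / n)


def learning_trend(values: Sequence[float], run_indices: Sequence[float]) -> Tuple[float, float]:
    """Pearson correlation (and two-sided p-value) of a metric with run index."""
    values = np.asarray(values, float)
    run_indices = np.asarray(run_indices, float)
    if len(values) < 3:
        raise ValueError("need at least 3 runs for a trend test")
    if np.ptp(values) == 0 or np.ptp(run_indices) == 0:
        warnings.warn("constant input; trend correlation undefined")
        return float("nan"), float("nan")
    r, p = scipy.stats.pearsonr(values, run_indices)
    return float(r), float(p)
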