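"""End-to-end study procedures on the synthetic fixtures.

These functions tie the pipeline stages together into the experiments the
package is validated with: between-session shift recovery by the adaptive
chain, the user-learning dissociation (accuracy ↑, test–train adaptation ↓,
class distinctiveness flat), EOG rejection sensitivity/specificity, and the
command-gate streaming/batch equivalence check.  Each is a pure function of
its seed and configuration and returns plain dictionaries of numbers.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import adapt, geometry as geo, metrics
from .classify import FgMDM
from .gating import GateConfig, gate_run
from .geometry import SPDSet
from .preprocessing import bandpass_array, eog_derivations, eog_reject, estimate_eog_thresholds
from .simulate import SimConfig, _class_means, _rng, _sample_around, apply_session_shift
from .simulate import CLASS_NAMES, simulate_user_adaptation, synthesize_eog

__all__ = [
    "adaptation_recovery_experiment",
    "user_learning_experiment",
    "eog_rejection_experiment",
    "gate_equivalence_experiment",
    "gate_reference_commands",
]


def _draw_session(
    cfg: SimConfig,
    rng: np.random.Generator,
    means: np.ndarray,
    n_per_class: int,
    session_id: str,
) -> Tuple[SPDSet, SPDSet]:
    """Labeled task covariances plus an eyes-open baseline set for one session."""
    mats, labels = [], []
    for k in range(cfg.n_classes):
        mats.append(_sample_around(rng, means[k], n_per_class, cfg.dispersion))
        labels += [CLASS_NAMES[k]] * n_per_class
    # interleave classes as a randomized cue order would (a class-blocked
    # stream would bias the unsupervised online mean tracking)
    order = rng.permutation(cfg.n_classes * n_per_class)
    covs = SPDSet(
        np.concatenate(mats)[order],
        labels=np.array(labels)[order],
        session_ids=np.array([session_id] * (cfg.n_classes * n_per_class)),
    )
    base_ref = cfg.baseline_scale * np.eye(cfg.n_channels)
    baseline = SPDSet(
        _sample_around(rng, base_ref, 40, cfg.baseline_dispersion),
        session_ids=np.array([session_id] * 40),
    )
    return covs, baseline


def adaptation_recovery_experiment(
    seed: int = 0, cfg: Optional[SimConfig] = None, n_test_per_class: int = 50
) -> Dict[str, float]:
    """Between-session shift recovery by baseline projection + adaptive rebias.

    A classifier is trained on session 1.  Session 2 is the same class
    structure transformed by a global congruence shift (with its baseline
    shifted identically).  Reported accuracies (%):

    * ``accuracy_noshift`` — held-out session-1 data, plain classifier;
    * ``accuracy_shifted_nonadaptive`` — session-2 data, plain classifier;
    * ``accuracy_shifted_adaptive`` — session-2 data through the adaptive
      chain (session-baseline projection, then online recentering by the
      incrementally tracked test mean) with a classifier trained on
      identically aligned session-1 data.
    """
    cfg = replace(cfg or SimConfig(), seed=seed)
    rng = _rng(cfg)
    means = _class_means(cfg)

    train, train_baseline = _draw_session(cfg, rng, means, cfg.n_epochs_per_class, "S01")
    holdout, _ = _draw_session(cfg, rng, means, n_test_per_class, "S01")

    # Session 2: identical structure, global congruence shift on data+baseline.
    test2, test2_baseline = _draw_session(cfg, rng, means, n_test_per_class, "S02")
    shift_seed = int(rng.integers(2**31))
    test2_shifted, w = apply_session_shift(test2, cfg.session_shift_magnitude, shift_seed)
    test2_baseline_shifted = SPDSet(
        geo.congruence(test2_baseline.mats, w), session_ids=test2_baseline.session_ids
    )

    # Plain (non-adaptive) classifier on raw covariances.
    plain = FgMDM().fit(train)
    acc_noshift = float(np.mean(plain.predict(holdout.mats) == holdout.labels))
    acc_shift_plain = float(np.mean(plain.predict(test2_shifted.mats) == test2_shifted.labels))

    # Adaptive chain: align training by its session baseline, recenter, train.
    proj1 = adapt.make_session_projector(train_baseline, "S01")
    train_aligned = adapt.apply_session_projection(proj1, train)
    train_mean = geo.karcher_mean(train_aligned.mats)
    train_centered = adapt.recenter(train_aligned, train_mean)
    model = FgMDM().fit(SPDSet(train_centered.mats, labels=train.labels))

    proj2 = adapt.make_session_projector(test2_baseline_shifted, "S02")
    pred, _, _ = adapt.online_adaptive_predict(
        model, proj2, test2_shifted, rebias=adapt.init_rebias(train_mean)
    )
    acc_adaptive = float(np.mean(pred == test2_shifted.labels))

    return {
        "accuracy_noshift": 100 * acc_noshift,
        "accuracy_shifted_nonadaptive": 100 * acc_shift_plain,
        "accuracy_shifted_adaptive": 100 * acc_adaptive,
        "nonadaptive_drop": 100 * (acc_noshift - acc_shift_plain),
        "adaptive_gap": 100 * abs(acc_noshift - acc_adaptive),
    }


def user_learning_experiment(
    seed: int = 0,
    cfg: Optional[SimConfig] = None,
    n_runs: int = 12,
    adaptation_rate: float = 1.0 / 12.0,
) -> Dict[str, object]:
    """The user-learning dissociation on simulated runs.

    A fixed classifier is trained once; each subsequent run the simulated
    user's global covariance shift relaxes toward the training distribution.
    Per run we measure classification accuracy, TTA against the training
    landmarks, and multi-class distinctiveness (classDis), all on batch-
    recentered covariances, and report their Pearson trends against run
    index.  Expected pattern: accuracy trend positive, TTA trend negative,
    classDis trend near zero.
    """
    cfg = replace(cfg or SimConfig(), seed=seed)
    train, runs, _ = simulate_user_adaptation(cfg, n_runs=n_runs, adaptation_rate=adaptation_rate)

    train_mean = geo.karcher_mean(train.mats)
    train_centered = adapt.recenter(train, train_mean)
    model = FgMDM().fit(train_centered)
    train_lm = metrics.compute_landmarks(train_centered)

    acc, tta_vals, cdis = [], [], []
    for run in runs:
        run_centered = adapt.recenter(run, geo.karcher_mean(run.mats))
        acc.append(float(np.mean(model.predict(run_centered.mats) == run.labels)))
        tta_vals.append(metrics.tta(train_lm, metrics.compute_landmarks(run_centered)))
        cdis.append(metrics.class_dis_multi(run_centered))

    idx = np.arange(1, n_runs + 1)
    rho_acc, p_acc = metrics.learning_trend(acc, idx)
    rho_tta, p_tta = metrics.learning_trend(tta_vals, idx)
    rho_cd, p_cd = metrics.learning_trend(cdis, idx)
    return {
        "accuracy": [100 * a for a in acc],
        "tta": tta_vals,
        "class_dis": cdis,
        "rho_accuracy": rho_acc,
        "rho_tta": rho_tta,
        "rho_class_dis": rho_cd,
        "p_accuracy": p_acc,
        "p_tta": p_tta,
        "p_class_dis": p_cd,
    }


def eog_rejection_experiment(
    seed: int = 0, cfg: Optional[SimConfig] = None, duration: float = 180.0
) -> Dict[str, float]:
    """Sensitivity and specificity of the EOG window rejection.

    Thresholds (mean + 3·std of the rectified derivations) are estimated
    from an artifact-sparse training stretch — the mean + 3·std rule is a
    *peak* detector, so the estimation data must be dominated by baseline
    ocular activity.  They are then applied to (a) an artifact-free
    recording — the fraction of 1 s windows rejected is the false-rejection
    rate — and (b) a recording with injected blinks/saccades — the fraction
    of windows containing an artifact peak that are rejected is the
    detection rate (%).
    """
    cfg = replace(cfg or SimConfig(), seed=seed)
    fs = cfg.fs
    win = int(fs)  # 1 s windows

    def derivations(eog: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        filt = bandpass_array(eog, fs, 1.0, 10.0, order=4)
        return eog_derivations(filt[:, 0], filt[:, 1], filt[:, 2])

    rng = _rng(cfg)
    train_eog, _ = synthesize_eog(duration, replace(cfg, eog_blink_rate=0.0), rng)
    th = estimate_eog_thresholds(*derivations(train_eog))

    clean_eog, _ = synthesize_eog(duration, replace(cfg, eog_blink_rate=0.0), rng)
    v, h = derivations(clean_eog)
    n_win = len(v) // win
    false_rej = np.mean(
        [eog_reject(v[i * win : (i + 1) * win], h[i * win : (i + 1) * win], th) for i in range(n_win)]
    )

    art_eog, intervals = synthesize_eog(duration, cfg, rng)
    v, h = derivations(art_eog)
    peaks = [0.5 * (a + b) for a, b in intervals]
    hits = total = 0
    for i in range(len(v) // win):
        if any(i <= p < i + 1.0 for p in peaks):
            total += 1
            if eog_reject(v[i * win : (i + 1) * win], h[i * win : (i + 1) * win], th):
                hits += 1
    detection = 100.0 * hits / max(total, 1)
    return {
        "blink_window_rejection_pct": detection,
        "false_rejection_pct": 100.0 * float(false_rej),
        "n_artifact_windows": float(total),
    }


def gate_reference_commands(
    stream: List[Tuple[object, float]], cfg: GateConfig
) -> List[Tuple[int, object]]:
    """Brute-force re-check of the gate over the full history at every step.

    At step t, the last N_e epochs are re-examined from scratch: all labels
    equal and all probabilities above the floor.  In reset mode an emission
    additionally requires that no emission occurred within the current
    qualifying run's last N_e epochs.  Independent of the streaming
    implementation; used as its oracle.
    """
    n, pc = cfg.n_consecutive, cfg.prob_floor
    out: List[Tuple[int, object]] = []
    qualify = [p > pc for _, p in stream]
    labels = [l for l, _ in stream]
    run_start = 0
    for t in range(len(stream)):
        starts_new_run = (
            t == 0 or not qualify[t - 1] or labels[t] != labels[t - 1]
        )
        if not qualify[t] or starts_new_run:
            run_start = t if qualify[t] else t + 1
        run_len = t - run_start + 1 if qualify[t] else 0
        if run_len >= n:
            if cfg.mode == "sliding":
                out.append((t, labels[t]))
            else:  # reset: emit every n-th epoch of a qualifying run
                if run_len % n == 0:
                    out.append((t, labels[t]))
    return out


def gate_equivalence_experiment(
    seed: int = 0, n_steps: int = 10_000, n_labels: int = 4
) -> Dict[str, float]:
    """Streaming gate vs. brute-force sliding-window oracle on random streams."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_labels, size=n_steps)
    # mostly-sticky labels so long streaks actually occur
    for i in range(1, n_steps):
        if rng.uniform() < 0.7:
            labels[i] = labels[i - 1]
    probs = rng.uniform(0.0, 1.0, size=n_steps)
    stream = list(zip(labels.tolist(), probs.tolist()))
    mismatches = 0
    n_commands = 0
    for mode in ("reset", "sliding"):
        cfg = GateConfig(n_consecutive=8, prob_floor=0.3, mode=mode)
        got = gate_run(stream, cfg)
        want = gate_reference_commands(stream, cfg)
        if got != want:
            mismatches += sum(a != b for a, b in zip(got, want)) + abs(len(got) - len(want))
        n_commands += len(got)
    return {"mismatches": float(mismatches), "n_commands": float(n_commands)}
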