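"""Unsupervised handling of EEG non-stationarity on the covariance manifold.

Two congruence-based alignments, both label-free:

* **Recentering (rebias)** — project covariances by the inverse square root
  of a Karcher-mean estimate so the set is centered at the identity; online,
  the test-set mean is tracked incrementally by geodesic interpolation with
  weight 1/(i+1), initialized at the training-set mean.
* **Session-baseline projection** — a per-session projector built from the
  Karcher mean of the session's eyes-open resting baseline maps every
  session (training and test alike) to a common reference, attacking
  between-session distribution shifts.

The classifier weights are never touched; only the projections applied to the
input covariances adapt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import geometry as geo
from .geometry import SPDSet

__all__ = [
    "RebiasState",
    "SessionProjector",
    "recenter",
    "init_rebias",
    "update_rebias",
    "make_session_projector",
    "apply_session_projection",
    "online_adaptive_predict",
]

logger = logging.getLogger(__name__)


@dataclass
class RebiasState:
    """Running Karcher-mean estimate of the (unseen) test set."""

    mean_estimate: np.ndarray
    count: int = 1

    def to_dict(self) -> dict:
        return {"mean_estimate": self.mean_estimate.tolist(), "count": self.count}

    @classmethod
    def from_dict(cls, d: dict) -> "RebiasState":
        return cls(np.asarray(d["mean_estimate"], float), int(d["count"]))


@dataclass
class SessionProjector:
    """Congruence projector built from one session's resting baseline."""

    baseline_mean: np.ndarray
    session_id: str


def recenter(covs: SPDSet, mean: np.ndarray) -> SPDSet:
    """Center a covariance set: each C becomes ``mean^{-1/2} C mean^{-1/2}``.

    If ``mean`` is the set's Karcher mean, the recentered set has Karcher
    mean at the identity; being a congruence, the map preserves all pairwise
    Riemannian distances.
    """
    imean = geo.invsqrtm(geo.check_spd(mean, "recentering mean"))
    return SPDSet(geo.congruence(covs.mats, imean), covs.labels, covs.session_ids)


def init_rebias(training_mean: np.ndarray) -> RebiasState:
    """Start the online mean tracker at the training-set Karcher mean."""
    return RebiasState(mean_estimate=geo.check_spd(training_mean, "training mean"), count=1)


def update_rebias(state: RebiasState, c_next: np.ndarray) -> RebiasState:
    """Incremental Karcher-mean update by weighted geodesic interpolation.

    ``C̄_{i+1} = γ(C̄_i, C_{i+1}; 1/(i+1))`` — over a commuting stream this
    reproduces the running geometric mean exactly.
    """
    t = 1.0 / (state.count + 1)
    new_mean = geo.geodesic_point(state.mean_estimate, c_next, t)
    return RebiasState(mean_estimate=new_mean, count=state.count + 1)


def make_session_projector(baseline: SPDSet, session_id: str = "S01") -> SessionProjector:
    """Projector from the Karcher mean of a session's eyes-open baseline epochs."""
    if len(baseline) == 0:
        raise ValueError("baseline covariance set is empty")
    return SessionProjector(baseline_mean=geo.karcher_mean(baseline.mats), session_id=session_id)


def apply_session_projection(p: SessionProjector, covs: SPDSet) -> SPDSet:
    """Project a session's covariances by its baseline: R̄^{-1/2} C R̄^{-1/2}.

    Refuses covariances tagged with a different session id, preventing a
    projector from being applied across sessions.
    """
    if covs.session_ids is not None:
        other = set(np.unique(covs.session_ids)) - {p.session_id}
        if other:
            raise ValueError(
                f"session mismatch: projector is for {p.session_id!r}, covariances "
                f"include {sorted(other)}"
            )
    return recenter(covs, p.baseline_mean)


def online_adaptive_predict(
    model,
    projector: Optional[SessionProjector],
    stream: SPDSet,
    rebias: Optional[RebiasState] = None,
    update_order: str = "predict_first",
    clean: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, RebiasState]:
    """Run the adaptive chain over an ordered covariance stream.

    For each incoming covariance: apply the session projection, recenter by
    the current rebias mean estimate, predict with the *fixed* classifier,
    then update the rebias estimate with the session-projected covariance.
    Prediction precedes the update so the output for epoch i never depends on
    epoch i itself; epochs flagged not-clean still receive a prediction but
    do not update the rebias state.

    Parameters
    ----------
    model : FgMDM or MDM
        Trained on session-projected, recentered training covariances.
    projector : SessionProjector or None
        This session's baseline projector (None to skip the baseline alignment).
    stream : SPDSet
        Ordered test covariances.
    rebias : RebiasState, optional
        Running mean state; defaults to the model-training global mean when
        available, else the identity.
    clean : bool array, optional
        Per-epoch artifact flags; rejected epochs do not update the state.

    Returns
    -------
    labels : ndarray (n,)
    probs : ndarray (n, n_classes) pseudo-probabilities
    rebias : final RebiasState
    """
    if update_order not in ("predict_first", "update_first"):
        raise ValueError("update_order must be 'predict_first' or 'update_first'")
    projected = (
        apply_session_projection(projector, stream) if projector is not None else stream
    )
    if rebias is None:
        base = getattr(getattr(model, "fgda_", None), "base_", None)
        rebias = init_rebias(base if base is not None else np.eye(stream.dim))
    if clean is None:
        clean = np.ones(len(stream), dtype=bool)

    labels: List = []
    probs: List[np.ndarray] = []
    for i in range(len(projected)):
        c = projected.mats[i]
        if update_order == "update_first" and clean[i]:
            rebias = update_rebias(rebias, c)
        ic = geo.invsqrtm(rebias.mean_estimate)
        c_centered = geo.congruence(c, ic)
        labels.append(model.predict(c_centered[None])[0])
        probs.append(model.predict_proba(c_centered[None])[0])
        if update_order == "predict_first" and clean[i]:
            rebias = update_rebias(rebias, c)

    labels = np.asarray(labels)
    counts = np.unique(labels, return_counts=True)[1]
    if len(labels) >= 20 and counts.max() / len(labels) > 0.8:
        logger.warning(
            "predicted-label distribution is highly skewed (%.0f%% one class); "
            "an over-represented rest class can bias the unsupervised rebias",
            100 * counts.max() / len(labels),
        )
    return labels, np.asarray(probs), rebias
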