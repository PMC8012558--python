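"""Riemannian classifiers for spatial covariance matrices.

* MDM — minimum distance to (Karcher) mean.
* FGDA — Fisher geodesic discriminant analysis: project log-mapped
  covariances in the tangent space at the global mean onto the span of the
  Fisher discriminant directions, and map back to the manifold.  The filter
  is an idempotent projector W; composing FGDA with MDM gives FgMDM.
* Pseudo-probabilities turning class distances into a normalized confidence.
* A 2-class CSP + LDA baseline on epoched signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from . import geometry as geo
from .geometry import SPDSet

__all__ = [
    "MDM",
    "FGDA",
    "FgMDM",
    "CSPLDA",
    "pseudo_probabilities",
    "tangent_vectorize",
    "tangent_unvectorize",
]

logger = logging.getLogger(__name__)


def tangent_vectorize(s: np.ndarray) -> np.ndarray:
    """Half-vectorize symmetric matrices with √2-weighted off-diagonals.

    The weighting makes the Euclidean inner product of the vectors equal to
    the Frobenius inner product of the matrices, so Euclidean discriminant
    analysis in the vector space respects the tangent-space metric.
    Accepts a single matrix or a stack.
    """
    s = np.asarray(s, float)
    d = s.shape[-1]
    iu = np.triu_indices(d)
    weights = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return s[..., iu[0], iu[1]] * weights


def tangent_unvectorize(v: np.ndarray, dim: int) -> np.ndarray:
    """Inverse of :func:`tangent_vectorize`."""
    v = np.asarray(v, float)
    iu = np.triu_indices(dim)
    weights = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    vals = v / weights
    out = np.zeros(v.shape[:-1] + (dim, dim))
    out[..., iu[0], iu[1]] = vals
    out[..., iu[1], iu[0]] = vals
    return out


def pseudo_probabilities(distances: np.ndarray) -> np.ndarray:
    """Normalize per-class scores into pseudo-class probabilities.

    ``p_i = min_j(d_j) / d_i`` and ``P_i = p_i / Σ p_i``: the nearest class
    gets the largest probability, and with N equal scores each class gets
    1/N — the floor probability of the selected class.  Zero scores get the
    whole mass (uniform over the zero set if several).
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    zero = d == 0
    if zero.any():
        return zero / zero.sum()
    p = d.min() / d
    return p / p.sum()


@dataclass
class MDM:
    """Minimum-distance-to-mean classifier on the SPD manifold.

    Training computes the Karcher mean of each class; prediction assigns the
    label of the nearest class mean under the affine-invariant distance.
    Ties go to the first class in ``classes_`` order (logged).
    """

    classes_: Optional[np.ndarray] = None
    means_: Optional[np.ndarray] = None

    def fit(self, covs: SPDSet) -> "MDM":
        if covs.labels is None:
            raise ValueError("MDM requires labeled covariances")
        self.classes_ = covs.classes()
        if len(self.classes_) < 2:
            raise ValueError("MDM requires at least 2 classes")
        self.means_ = np.array(
            [geo.karcher_mean(covs.mats[covs.labels == c]) for c in self.classes_]
        )
        return self

    def transform(self, mats: np.ndarray) -> np.ndarray:
        """Distances of each covariance to each class mean, shape (n, n_classes)."""
        mats = np.asarray(mats, float)
        if mats.ndim == 2:
            mats = mats[None]
        return np.stack([geo.pairwise_distances(mats, m) for m in self.means_], axis=1)

    def predict(self, mats: np.ndarray) -> np.ndarray:
        d = self.transform(mats)
        idx = np.argmin(d, axis=1)
        ties = (d == d[np.arange(len(d)), idx][:, None]).sum(axis=1) > 1
        if ties.any():
            logger.info("MDM: %d tie(s) broken toward the first class in order", ties.sum())
        return self.classes_[idx]

    def predict_proba(self, mats: np.ndarray) -> np.ndarray:
        """Pseudo-probabilities from squared distances to the class means."""
        d = self.transform(mats)
        return np.apply_along_axis(pseudo_probabilities, 1, d**2)


@dataclass
class FGDA:
    """Fisher geodesic discriminant analysis filter.

    Covariances are log-mapped at the global Karcher mean ``base_``,
    vectorized, projected onto the span of the (≤ n_classes − 1) Fisher
    discriminant directions by the idempotent projector ``w_``, and exp-mapped
    back to the manifold.  The within-class scatter is regularized
    (Ledoit–Wolf by default) so the discriminant is well-posed even with few
    epochs.
    """

    shrinkage: Optional[float] = None  # None → Ledoit–Wolf "auto"
    base_: Optional[np.ndarray] = None
    w_: Optional[np.ndarray] = None

    def fit(self, covs: SPDSet) -> "FGDA":
        if covs.labels is None:
            raise ValueError("FGDA requires labeled covariances")
        classes = covs.classes()
        if len(classes) < 2:
            raise ValueError("FGDA requires at least 2 classes")
        self.base_ = geo.karcher_mean(covs.mats)
        vecs = self._tangent_vectors(covs.mats)
        shrink = "auto" if self.shrinkage is None else self.shrinkage
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrink)
        try:
            lda.fit(vecs, covs.labels)
        except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
            raise ValueError(
                "singular within-class scatter; pass shrinkage > 0"
            ) from err
        a = lda.scalings_[:, : len(classes) - 1]
        self.w_ = a @ np.linalg.solve(a.T @ a, a.T)
        return self

    def _tangent_vectors(self, mats: np.ndarray) -> np.ndarray:
        ibase = geo.invsqrtm(self.base_)
        return tangent_vectorize(geo.logm(ibase @ np.asarray(mats, float) @ ibase))

    def transform(self, mats: np.ndarray) -> np.ndarray:
        """Geodesic filtering: project tangent vectors, map back to SPD."""
        mats = np.asarray(mats, float)
        single = mats.ndim == 2
        if single:
            mats = mats[None]
        vecs = self._tangent_vectors(mats) @ self.w_.T
        s = tangent_unvectorize(vecs, self.base_.shape[0])
        sbase = geo.sqrtm(self.base_)
        out = sbase @ geo.expm(s) @ sbase
        return out[0] if single else out


@dataclass
class FgMDM:
    """FGDA geodesic filtering composed with MDM classification."""

    shrinkage: Optional[float] = None
    fgda_: Optional[FGDA] = None
    mdm_: Optional[MDM] = None

    def fit(self, covs: SPDSet) -> "FgMDM":
        self.fgda_ = FGDA(shrinkage=self.shrinkage).fit(covs)
        filtered = SPDSet(self.fgda_.transform(covs.mats), labels=covs.labels)
        self.mdm_ = MDM().fit(filtered)
        return self

    @property
    def classes_(self) -> np.ndarray:
        return self.mdm_.classes_

    def transform(self, mats: np.ndarray) -> np.ndarray:
        mats = np.asarray(mats, float)
        if mats.ndim == 2:
            mats = mats[None]
        return self.mdm_.transform(self.fgda_.transform(mats))

    def predict(self, mats: np.ndarray) -> np.ndarray:
        mats = np.asarray(mats, float)
        if mats.ndim == 2:
            mats = mats[None]
        return self.mdm_.predict(self.fgda_.transform(mats))

    def predict_proba(self, mats: np.ndarray) -> np.ndarray:
        d = self.transform(mats)
        return np.apply_along_axis(pseudo_probabilities, 1, d**2)


@dataclass
class CSPLDA:
    """2-class CSP + LDA baseline on epoched signals.

    CSP filters come from the generalized eigendecomposition of the two class
    covariance matrices; the 3 largest- and 3 smallest-eigenvalue filters are
    kept (6 by default).  Features are log-variances of the spatially
    filtered epochs, classified with LDA.
    """

    n_filters: int = 6
    filters_: Optional[np.ndarray] = None
    classes_: Optional[np.ndarray] = None
    lda_: Optional[LinearDiscriminantAnalysis] = None

    def fit(self, epochs: np.ndarray, labels: Sequence) -> "CSPLDA":
        """``epochs``: (n_epochs, n_channels, n_times)."""
        labels = np.asarray(labels)
        self.classes_ = np.unique(labels)
        if len(self.classes_) != 2:
            raise ValueError("the CSP+LDA baseline supports exactly 2 classes")
        if self.n_filters % 2:
            raise ValueError("n_filters must be even")
        covs = []
        for c in self.classes_:
            x = epochs[labels == c]
            cc = np.mean([e @ e.T / np.trace(e @ e.T) for e in x], axis=0)
            covs.append(cc)
        w_all, v = scipy.linalg.eigh(covs[0], covs[0] + covs[1])
        order = np.argsort(w_all)
        half = self.n_filters // 2
        keep = np.concatenate([order[:half], order[-half:]])
        self.filters_ = v[:, keep].T
        feats = self._features(epochs)
        self.lda_ = LinearDiscriminantAnalysis().fit(feats, labels)
        return self

    def _features(self, epochs: np.ndarray) -> np.ndarray:
        filtered = np.einsum("fc,ect->eft", self.filters_, epochs)
        return np.log(np.var(filtered, axis=2) + 1e-30)

    def predict(self, epochs: np.ndarray) -> np.ndarray:
        return self.lda_.predict(self._features(epochs))
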