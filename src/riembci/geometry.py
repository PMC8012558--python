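"""Affine-invariant Riemannian geometry on symmetric positive definite matrices.

EEG epochs are summarized by their spatial covariance matrices (SCMs), which
live on the manifold of symmetric positive definite (SPD) matrices.  This
module provides the metric primitives everything else builds on: the
affine-invariant distance, the Karcher (Fréchet) mean and variance, geodesics,
congruence transforms and the log/exp maps between the manifold and its
tangent spaces.

All functions accept plain numpy arrays.  Stacks of matrices use the
``(n, d, d)`` layout throughout; matrix functions are evaluated through
batched symmetric eigendecompositions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "SPDSet",
    "check_spd",
    "sqrtm",
    "invsqrtm",
    "logm",
    "expm",
    "powm",
    "riemannian_distance",
    "pairwise_distances",
    "karcher_mean",
    "riemannian_variance",
    "geodesic_point",
    "congruence",
    "log_map",
    "exp_map",
]

# Eigenvalues below this are clipped (with a warning) instead of failing, so
# that near-singular shrunk covariances survive the matrix functions.
EIG_CLIP = 1e-12
# Relative asymmetry below this is silently repaired; above, it is an error.
SYM_TOL = 1e-6


class NonConvergenceError(RuntimeError):
    """Karcher-mean iteration failed to reach the requested tolerance."""


@dataclass
class SPDSet:
    """An ordered collection of SPD matrices with optional annotations.

    Parameters
    ----------
    mats : ndarray, shape (n, d, d)
        The SPD samples (e.g. spatial covariance matrices, in μV²).
    labels : ndarray of shape (n,), optional
        Class identifier per sample.
    session_ids : ndarray of shape (n,), optional
        Session identifier per sample.
    """

    mats: np.ndarray
    labels: Optional[np.ndarray] = None
    session_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.mats = np.asarray(self.mats, dtype=float)
        if self.mats.ndim != 3 or self.mats.shape[1] != self.mats.shape[2]:
            raise ValueError("mats must have shape (n, d, d)")
        for name in ("labels", "session_ids"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val)
                if len(val) != len(self.mats):
                    raise ValueError(f"{name} length {len(val)} != number of samples {len(self.mats)}")
                setattr(self, name, val)

    def __len__(self) -> int:
        return len(self.mats)

    @property
    def dim(self) -> int:
        return self.mats.shape[1]

    def subset(self, index) -> "SPDSet":
        return SPDSet(
            self.mats[index],
            None if self.labels is None else self.labels[index],
            None if self.session_ids is None else self.session_ids[index],
        )

    def classes(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("SPDSet has no labels")
        return np.unique(self.labels)


def _symmetrize(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    mt = np.swapaxes(m, -1, -2)
    asym = np.max(np.abs(m - mt))
    scale = max(np.max(np.abs(m)), np.finfo(float).tiny)
    if asym / scale > SYM_TOL:
        raise ValueError(
            f"matrix is not symmetric (relative asymmetry {asym / scale:.2e} > {SYM_TOL})"
        )
    return 0.5 * (m + mt)


def check_spd(m: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate that ``m`` is SPD; returns the symmetrized matrix.

    Raises ``ValueError`` naming the offending eigenvalue otherwise.
    """
    m = _symmetrize(m)
    w = np.linalg.eigvalsh(m)
    if w.min() <= 0:
        raise ValueError(f"{name} is not positive definite: smallest eigenvalue {w.min():.3e}")
    return m


def _eigh_fun(m: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of symmetric matrices.

    Works on a single ``(d, d)`` matrix or a stack ``(..., d, d)``.
    Eigenvalues are clipped at ``EIG_CLIP`` (warning) to survive numerically
    semidefinite inputs.
    """
    m = _symmetrize(m)
    w, v = np.linalg.eigh(m)
    if w.min() < EIG_CLIP:
        warnings.warn(
            f"eigenvalue {w.min():.3e} below clip threshold {EIG_CLIP:g}; clipping",
            RuntimeWarning,
            stacklevel=3,
        )
        w = np.clip(w, EIG_CLIP, None)
    return (v * fun(w)[..., None, :]) @ np.swapaxes(v, -1, -2)


def sqrtm(m: np.ndarray) -> np.ndarray:
    """Symmetric matrix square root."""
    return _eigh_fun(m, np.sqrt)


def invsqrtm(m: np.ndarray) -> np.ndarray:
    """Symmetric inverse matrix square root."""
    return _eigh_fun(m, lambda w: 1.0 / np.sqrt(w))


def logm(m: np.ndarray) -> np.ndarray:
    """Symmetric matrix logarithm."""
    return _eigh_fun(m, np.log)


def expm(m: np.ndarray) -> np.ndarray:
    """Symmetric matrix exponential (no positivity requirement on input)."""
    m = 0.5 * (np.asarray(m, float) + np.swapaxes(np.asarray(m, float), -1, -2))
    w, v = np.linalg.eigh(m)
    return (v * np.exp(w)[..., None, :]) @ np.swapaxes(v, -1, -2)


def powm(m: np.ndarray, t: float) -> np.ndarray:
    """Symmetric matrix power ``m**t`` for SPD ``m``."""
    return _eigh_fun(m, lambda w: w**t)


def riemannian_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between two SPD matrices.

    ``d(A, B) = || log(A^{-1/2} B A^{-1/2}) ||_F = sqrt(sum_l log² λ_l)``
    with λ_l the (positive) eigenvalues of ``A^{-1/2} B A^{-1/2}``, equal to
    the generalized eigenvalues of the pencil (B, A).
    """
    a = check_spd(a, "first argument")
    b = check_spd(b, "second argument")
    import scipy.linalg

    w = scipy.linalg.eigh(b, a, eigvals_only=True)
    w = np.clip(w, EIG_CLIP, None)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def pairwise_distances(mats: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Distances from each matrix in a stack to a single SPD reference."""
    iref = invsqrtm(check_spd(ref, "reference"))
    inner = iref @ np.asarray(mats, float) @ iref
    w = np.linalg.eigvalsh(0.5 * (inner + np.swapaxes(inner, -1, -2)))
    w = np.clip(w, EIG_CLIP, None)
    return np.sqrt(np.sum(np.log(w) ** 2, axis=-1))


def _as_stack(set_or_mats) -> np.ndarray:
    if isinstance(set_or_mats, SPDSet):
        return set_or_mats.mats
    return np.asarray(set_or_mats, dtype=float)


def karcher_mean(
    set_or_mats,
    tol: float = 1e-8,
    max_iter: int = 200,
    init: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Karcher/Fréchet mean of a set of SPD matrices.

    Gradient-descent fixed-point scheme with unit step: at the current
    estimate M, average the log-maps of all samples in the tangent space at M
    and exp-map the average back, until the Frobenius norm of the tangent mean
    falls below ``tol``.

    Raises
    ------
    NonConvergenceError
        If the tangent-gradient norm is still above ``tol`` after
        ``max_iter`` iterations.
    """
    mats = _as_stack(set_or_mats)
    if mats.ndim == 2:
        mats = mats[None]
    if len(mats) == 0:
        raise ValueError("cannot average an empty set")
    if len(mats) == 1:
        return check_spd(mats[0])
    if tol <= 0:
        raise ValueError("tol must be positive")

    mean = np.mean(mats, axis=0) if init is None else np.asarray(init, float)
    grad_norm = np.inf
    for _ in range(max_iter):
        imean = invsqrtm(mean)
        smean = sqrtm(mean)
        tangent = logm(imean @ mats @ imean).mean(axis=0)
        grad_norm = float(np.linalg.norm(tangent))
        if grad_norm < tol:
            return 0.5 * (mean + mean.T)
        mean = smean @ expm(tangent) @ smean
    raise NonConvergenceError(
        f"Karcher mean did not converge in {max_iter} iterations "
        f"(last gradient norm {grad_norm:.3e}, tol {tol:g})"
    )


def riemannian_variance(set_or_mats, mean: np.ndarray) -> float:
    """Fréchet variance: mean squared Riemannian distance around ``mean``.

    ``mean`` is expected (not enforced) to be the Karcher mean of the set.
    """
    mats = _as_stack(set_or_mats)
    if len(mats) == 0:
        raise ValueError("cannot compute the variance of an empty set")
    d = pairwise_distances(mats, mean)
    return float(np.mean(d**2))


def geodesic_point(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Point at fraction ``t`` along the geodesic from ``a`` to ``b``.

    ``γ(t) = A^{1/2} (A^{-1/2} B A^{-1/2})^t A^{1/2}``, with γ(0)=A, γ(1)=B.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must lie in [0, 1], got {t}")
    a = check_spd(a, "first endpoint")
    b = check_spd(b, "second endpoint")
    sa, isa = sqrtm(a), invsqrtm(a)
    return sa @ powm(isa @ b @ isa, t) @ sa


def congruence(c: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Congruence transform ``W C Wᵀ`` of an SPD matrix (or stack) by W."""
    w = np.asarray(w, dtype=float)
    if abs(np.linalg.det(w)) < 1e-300:
        raise ValueError("congruence matrix is singular")
    c = np.asarray(c, dtype=float)
    out = w @ c @ w.T
    return 0.5 * (out + np.swapaxes(out, -1, -2))


def log_map(base: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Logarithmic map of ``c`` (SPD, or stack) at ``base``: a tangent vector.

    ``Log_B(C) = B^{1/2} log(B^{-1/2} C B^{-1/2}) B^{1/2}`` (a symmetric
    matrix, not necessarily positive).
    """
    base = check_spd(base, "base")
    sb, isb = sqrtm(base), invsqrtm(base)
    return sb @ logm(isb @ np.asarray(c, float) @ isb) @ sb


def exp_map(base: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Exponential map of the symmetric tangent vector ``v`` at ``base``."""
    base = check_spd(base, "base")
    v = _symmetrize(v)
    sb, isb = sqrtm(base), invsqrtm(base)
    return sb @ expm(isb @ v @ isb) @ sb
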