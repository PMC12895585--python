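"""PCA feature extraction from dynamic FC matrices.

Per participant, the K x M window-wise FC matrix X (K = 15 pairs,
M = 131 windows) is decomposed by PCA over the window dimension: the
M x M covariance matrix of X's columns (each window variable centred
over the 15 pairs) is eigendecomposed via SVD, giving eigenvalues
kappa_1 >= ... >= kappa_M and an orthonormal eigenvector matrix U.  The
cumulative contribution rate

    CCR(N) = sum_{n<=N} kappa_n / sum_{n<=M} kappa_n * 100%

selects a single cohort-wide N (smallest N whose cohort-mean CCR reaches
the 90-95% band), and each participant's reduced matrix is

    D = X @ U[:, :N]        (K x N)

Because only K = 15 pairs feed an M x M covariance, at most K - 1 = 14
eigenvalues are nonzero; N is capped at 14.

Entries of D are sign-indefinite; for interpretability the cohort's D
matrices are shifted by subtracting the single global minimum so the
smallest entry becomes exactly zero.  Rank-based analyses are invariant
to this shift; inside cross-validation the constant must be computed on
training participants only (see the classifier module).

Per-participant PCA makes eigenvector signs arbitrary; each column of U
has its sign fixed so that its largest-magnitude loading is positive.
Cross-participant comparison of D entries therefore rests on this
deterministic convention — an assumption of the method itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .connectivity import DynamicFcSeries

MAX_COMPONENTS = 14  # rank bound: K - 1 with K = 15 pairs


@dataclass
class PcaDecomposition:
    eigenvalues: np.ndarray  # length M, descending, >= 0
    eigenvectors: np.ndarray  # M x M, orthonormal columns

    @property
    def ccr_curve(self) -> np.ndarray:
        """CCR(N) in percent for N = 1..M."""
        total = self.eigenvalues.sum()
        return np.cumsum(self.eigenvalues) / total * 100.0


@dataclass
class PcFeatureMatrix:
    D: np.ndarray  # K x N
    n_components: int
    shift_constant: float
    feature_labels: list[str]


def pca_decompose(dyn: DynamicFcSeries | np.ndarray) -> PcaDecomposition:
    """Eigendecomposition of the window-covariance of X, via SVD.

    Columns of X (window variables) are centred over the K pairs; the
    covariance is Xc^T Xc / (K - 1).  SVD of Xc gives the eigenvectors
    (right singular vectors, including an orthonormal completion of the
    null space) and eigenvalues s^2 / (K - 1), padded with zeros up to M.
    """
    X = dyn.X if isinstance(dyn, DynamicFcSeries) else np.asarray(dyn, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("dynamic FC matrix contains non-finite values")
    K, M = X.shape
    if M < 2:
        raise ValueError("need at least 2 windows")
    Xc = X - X.mean(axis=0, keepdims=True)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=True)
    eigenvalues = np.zeros(M)
    eigenvalues[: s.size] = s**2 / (K - 1)
    U = Vt.T
    # deterministic sign: largest-|loading| entry of each column positive
    flip = U[np.argmax(np.abs(U), axis=0), np.arange(M)] < 0
    U[:, flip] *= -1.0
    return PcaDecomposition(eigenvalues=eigenvalues, eigenvectors=U)


def ccr(eigenvalues: np.ndarray, n: int) -> float:
    """Cumulative contribution rate of the first ``n`` eigenvalues, in %."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if not 1 <= n <= eigenvalues.size:
        raise ValueError(f"N = {n} outside 1..{eigenvalues.size}")
    return float(eigenvalues[:n].sum() / eigenvalues.sum() * 100.0)


def select_n_components(
    decompositions: Sequence[PcaDecomposition],
    lo: float = 90.0,
    hi: float = 95.0,
    cap: int = MAX_COMPONENTS,
) -> tuple[int, np.ndarray]:
    """Single cohort-wide N: smallest N with mean CCR(N) >= ``lo``.

    Returns (N, cohort-mean CCR curve).  If even the mean CCR at ``cap``
    stays below ``lo``, the cap is returned (the rank bound makes CCR(14)
    equal 100% in exact arithmetic, so this is a numerical safeguard).
    A mean CCR(N) above ``hi`` is allowed — the band is a target, not a
    constraint — and left to the caller to log.
    """
    if not decompositions:
        raise ValueError("empty cohort")
    curves = np.stack([d.ccr_curve for d in decompositions])
    mean_curve = curves.mean(axis=0)
    reached = np.flatnonzero(mean_curve[:cap] >= lo)
    n = int(reached[0]) + 1 if reached.size else cap
    return n, mean_curve


def project(
    dyn: DynamicFcSeries | np.ndarray, decomposition: PcaDecomposition, n: int
) -> np.ndarray:
    """Reduced matrix D = X @ U[:, :n] (K x n)."""
    X = dyn.X if isinstance(dyn, DynamicFcSeries) else np.asarray(dyn, dtype=float)
    U = decomposition.eigenvectors
    if not 1 <= n <= U.shape[1]:
        raise ValueError(f"N = {n} outside 1..{U.shape[1]}")
    if X.shape[1] != U.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} windows but eigenvectors are {U.shape[0]}-dimensional"
        )
    return X @ U[:, :n]


def shift_nonnegative(
    d_matrices: Sequence[np.ndarray],
) -> tuple[list[np.ndarray], float]:
    """Subtract the cohort-wide global minimum from every D entry.

    Returns the shifted matrices and the shift constant (the negated
    global minimum).  All pairwise differences — hence all rank-based
    statistics — are preserved; the new global minimum is exactly 0.
    """
    if not d_matrices:
        raise ValueError("no D matrices to shift")
    global_min = min(float(np.min(d)) for d in d_matrices)
    return [d - global_min for d in d_matrices], -global_min
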