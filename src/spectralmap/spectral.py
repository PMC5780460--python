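"""Spectral primitives: eigendecomposition with fixed conventions,
polynomials of matrices, the walk-weight oracle, and the matrix-correlation
quality metric.

The mapping rests on a basic identity of spectral graph theory: the (i, j)
entry of the l-th power of a weighted adjacency matrix S equals the sum of
the weights of all walks of length l from i to j, where the weight of a walk
is the product of the traversed edge weights.  ``walk_weight_sum`` computes
that sum by explicit enumeration and serves as an exponential-time oracle
against which the linear-algebra route is verified.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EigenSystem",
    "PolynomialMap",
    "eigendecompose",
    "matrix_polynomial",
    "walk_weight_sum",
    "ucorr",
    "correlation_matrix",
]

#: gap below which adjacent eigenvalues are flagged as numerically degenerate
DEGENERACY_RTOL = 1e-10


def fix_eigenvector_signs(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Ties are broken by the lowest index (``argmax`` convention).  Eigenvector
    signs are arbitrary; the mapped matrix U f(L) U^T is sign-invariant but
    the rotation R = U V^T and the eigenmode weight matrix W = V^T R V are
    not, so a fixed convention makes those outputs reproducible.
    """
    V = V.copy()
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


@dataclass
class EigenSystem:
    """Eigenvalues (descending) and sign-fixed orthonormal eigenvectors."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]

    def reconstruct(self) -> np.ndarray:
        V, lam = self.eigenvectors, self.eigenvalues
        return (V * lam) @ V.T


def eigendecompose(X) -> EigenSystem:
    """Symmetric eigendecomposition with descending order and fixed signs.

    Emits a warning when adjacent eigenvalues are numerically degenerate
    (the descending pairing is then arbitrary within the cluster; no
    re-pairing search is attempted).
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite entries")
    scale = max(1.0, float(np.abs(X).max()))
    if float(np.abs(X - X.T).max()) > 1e-10 * scale:
        raise ValueError("matrix is not symmetric")
    lam, V = np.linalg.eigh((X + X.T) / 2.0)
    lam, V = lam[::-1].copy(), V[:, ::-1].copy()
    V = fix_eigenvector_signs(V)
    lmax = float(np.abs(lam).max()) if lam.size else 0.0
    if lam.size > 1 and np.any(np.abs(np.diff(lam)) <= DEGENERACY_RTOL * max(lmax, 1e-300)):
        warnings.warn(
            "near-degenerate eigenvalues: descending pairing is arbitrary "
            "within the degenerate cluster",
            RuntimeWarning,
            stacklevel=2,
        )
    return EigenSystem(eigenvalues=lam, eigenvectors=V)


@dataclass
class PolynomialMap:
    """Polynomial f(x) = sum_i c_i (x / s)^i on a conditioned eigenvalue scale.

    ``coefficients`` live on the conditioned scale (eigenvalues divided by
    ``eigenvalue_scale`` before powering); raw powers of eigenvalues up to
    k ~ 10 are severely ill-conditioned, and dividing by the spectral radius
    is an exact reparameterization.  ``raw_coefficients`` maps back to the
    ordinary basis a_i with f(x) = sum_i a_i x^i.
    """

    coefficients: np.ndarray
    eigenvalue_scale: float = 1.0

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        if c.ndim != 1 or not np.all(np.isfinite(c)):
            raise ValueError("coefficients must be a finite 1-D vector")
        if not (self.eigenvalue_scale > 0):
            raise ValueError("eigenvalue_scale must be positive")
        self.coefficients = c

    @property
    def k(self) -> int:
        return self.coefficients.shape[0] - 1

    @property
    def raw_coefficients(self) -> np.ndarray:
        return self.coefficients / self.eigenvalue_scale ** np.arange(self.k + 1)

    @classmethod
    def from_raw(cls, raw, eigenvalue_scale: float = 1.0) -> "PolynomialMap":
        raw = np.atleast_1d(np.asarray(raw, dtype=float))
        scaled = raw * eigenvalue_scale ** np.arange(raw.shape[0])
        return cls(scaled, eigenvalue_scale)

    def __call__(self, x):
        """Evaluate f at scalar or array eigenvalue arguments (raw scale)."""
        t = np.asarray(x, dtype=float) / self.eigenvalue_scale
        out = np.zeros_like(t, dtype=float)
        for c in self.coefficients[::-1]:  # Horner
            out = out * t + c
        return out


def matrix_polynomial(S, poly: PolynomialMap, method: str = "spectral") -> np.ndarray:
    """Evaluate Omega = f(S) = sum_i a_i S^i for symmetric S.

    ``method="spectral"`` computes V f(Lambda) V^T from the eigensystem;
    ``method="powers"`` accumulates explicit matrix powers.  The two routes
    agree to rounding and the equivalence is part of the test surface.
    """
    X = np.asarray(getattr(S, "values", S), dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {X.shape}")
    if method == "spectral":
        eig = eigendecompose(X)
        fvals = poly(eig.eigenvalues)
        V = eig.eigenvectors
        Om = (V * fvals) @ V.T
        return (Om + Om.T) / 2.0
    if method == "powers":
        n = X.shape[0]
        a = poly.raw_coefficients
        Om = a[0] * np.eye(n)
        P = np.eye(n)
        for i in range(1, a.shape[0]):
            P = P @ X
            Om = Om + a[i] * P
        return (Om + Om.T) / 2.0
    raise ValueError(f"unknown method {method!r}")


def walk_weight_sum(S, source: int, target: int, length: int) -> float:
    """Sum of the weights of all walks of a given length by brute force.

    A walk of length l from i to j is an ordered sequence of l+1 nodes each
    consecutive pair of which is an edge; its weight is the product of the
    traversed edge weights.  Enumeration is exponential in l, so this oracle
    is restricted to test scale (n <= 12, l <= 8); it must equal
    ``[S^l]_{ij}``.
    """
    X = np.asarray(getattr(S, "values", S), dtype=float)
    n = X.shape[0]
    if n > 12 or length > 8:
        raise ValueError("walk oracle restricted to n <= 12 and l <= 8")
    if length < 0:
        raise ValueError("walk length must be >= 0")
    if not (0 <= source < n and 0 <= target < n):
        raise IndexError("source/target out of range")
    if length == 0:
        return 1.0 if source == target else 0.0
    total = 0.0
    for mids in itertools.product(range(n), repeat=length - 1):
        nodes = (source, *mids, target)
        w = 1.0
        for a, b in zip(nodes[:-1], nodes[1:]):
            w *= X[a, b]
            if w == 0.0:
                break
        total += w
    return total


def ucorr(X, Y) -> float:
    """Pearson correlation of the strict upper-triangular entries of X and Y.

    The diagonal is excluded.  This is the mapping-quality metric used
    throughout the evaluation toolkit.
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    Y = np.asarray(getattr(Y, "values", Y), dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("inputs must be square matrices")
    n = X.shape[0]
    if n < 3:
        raise ValueError("ucorr requires n >= 3 (at least 3 upper-triangular entries)")
    iu = np.triu_indices(n, k=1)
    x, y = X[iu], Y[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a vectorized upper triangle")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_matrix(ts) -> "FunctionalMatrix":
    """Pearson correlation matrix of region-wise time series."""
    from .io import BoldSeries, FunctionalMatrix

    if not isinstance(ts, BoldSeries):
        ts = BoldSeries(ts)
    F = np.corrcoef(ts.signals)
    F = np.clip((F + F.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(F, 1.0)
    return FunctionalMatrix(F)
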