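"""Per-subject (individual) spectral mapping, solved in closed form.

Model
-----
Given a subject's structural adjacency matrix S and functional correlation
matrix F (both n x n symmetric), the mapping

    F_hat = R (a_0 I + a_1 S + ... + a_k S^k) R^T,   R R^T = R^T R = I,

is fitted by minimizing the squared Frobenius norm ||F_hat - F||_F^2.  With
S = V Lambda V^T and F = U Phi U^T (eigenvalues in descending order) the
minimizer has a closed form: the coefficients a* solve the Vandermonde
least-squares problem L a = phi built from the structural eigenvalues, and
the optimal rotation is the orthogonal Procrustes alignment R* = U V^T.
The orthogonality constraint admits reflections (det R = -1); U V^T may
carry either sign and no determinant restriction is imposed.

A rank-constrained variant limits the number of eigenmode pairs that are
freely aligned: only the leading m structural/functional eigenvector pairs
(by descending eigenvalue) use the Procrustes alignment, while the
orthogonal complement is completed deterministically from the remaining
structural eigenvectors, so the extra degrees of freedom contributed by the
rotation can be dialled down to probe overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import StructuralMatrix, FunctionalMatrix
from .spectral import EigenSystem, PolynomialMap, eigendecompose, ucorr

__all__ = [
    "IndividualSpectralMapping",
    "IndividualMappingResults",
    "fit_individual",
    "fit_individual_rank_constrained",
    "map_functional",
    "eigenmode_weights",
]


def _values(X) -> np.ndarray:
    return np.asarray(getattr(X, "values", X), dtype=float)


def _fit_coefficients(lam: np.ndarray, phi: np.ndarray, k: int) -> PolynomialMap:
    """Solve the Vandermonde least-squares problem on a conditioned scale.

    Eigenvalues are divided by their largest magnitude before powering
    (exact reparameterization); the system is solved by orthogonal
    factorization (``lstsq``) rather than the normal-equations inverse.
    """
    scale = float(np.abs(lam).max())
    if scale == 0.0:
        scale = 1.0
    t = lam / scale
    L = np.vander(t, N=k + 1, increasing=True)
    coeffs, *_ = np.linalg.lstsq(L, phi, rcond=None)
    return PolynomialMap(coeffs, eigenvalue_scale=scale)


def _rank_constrained_rotation(U: np.ndarray, V: np.ndarray, m: int) -> np.ndarray:
    """Rotation aligning only the leading m eigenmode pairs.

    R_m = U_m V_m^T + U_bar V_bar^T with V_bar the trailing structural
    eigenvectors and U_bar the orthonormalized residuals of those same
    vectors against span(U_m) (QR in descending-eigenvalue order, signs
    fixed).  The complement therefore uses no functional eigenvector beyond
    the first m; at m = n the construction reduces exactly to U V^T.
    """
    n = U.shape[0]
    if not (1 <= m <= n):
        raise ValueError(f"rank m must satisfy 1 <= m <= n, got m={m}, n={n}")
    if m == n:
        return U @ V.T
    Um, Vm = U[:, :m], V[:, :m]
    Vbar = V[:, m:]
    resid = Vbar - Um @ (Um.T @ Vbar)
    Ubar, r = np.linalg.qr(resid)
    d = np.sign(np.diag(r))
    d[d == 0] = 1.0
    Ubar = Ubar * d
    return Um @ Vm.T + Ubar @ Vbar.T


@dataclass
class IndividualMappingResults:
    """Fitted per-subject mapping: polynomial coefficients and rotation.

    Constructed by :meth:`IndividualSpectralMapping.fit`, by
    :func:`spectralmap.io.read_mapping`, or directly (planted ground-truth
    mappings in the synthetic module).
    """

    poly: PolynomialMap
    rotation: np.ndarray
    rank_m: int
    n: int
    k: int
    fit_residual: float
    model: Optional["IndividualSpectralMapping"] = field(default=None, repr=False)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (self.n, self.n):
            raise ValueError(f"rotation has shape {R.shape}, expected ({self.n}, {self.n})")
        err = max(
            float(np.abs(R @ R.T - np.eye(self.n)).max()),
            float(np.abs(R.T @ R - np.eye(self.n)).max()),
        )
        if err > 1e-8:
            raise ValueError(f"rotation is not orthogonal (max deviation {err:.2e})")
        if self.fit_residual < 0:
            raise ValueError("fit_residual must be non-negative")
        self.rotation = R

    @property
    def params(self) -> np.ndarray:
        """Polynomial coefficients a_0..a_k on the raw eigenvalue scale."""
        return self.poly.raw_coefficients

    def predict(self, S=None) -> np.ndarray:
        """Mapped functional matrix F_hat = R f(S) R^T.

        With no argument, predicts on the training structural matrix.
        Evaluated through S's eigensystem: R V f(Lambda) V^T R^T.
        """
        if S is None:
            if self.model is None:
                raise ValueError("no training data attached; pass S explicitly")
            S = self.model.structural
        X = _values(S)
        if X.shape != (self.n, self.n):
            raise ValueError(f"structural matrix has shape {X.shape}, model has n={self.n}")
        eig = eigendecompose(X)
        fvals = self.poly(eig.eigenvalues)
        B = self.rotation @ eig.eigenvectors
        Fhat = (B * fvals) @ B.T
        return (Fhat + Fhat.T) / 2.0

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    def ucorr_insample(self) -> float:
        """Matrix-correlation quality against the training functional matrix."""
        if self.model is None:
            raise ValueError("no training data attached")
        return ucorr(self.fittedvalues, self.model.functional)

    def eigenmode_weights(self) -> np.ndarray:
        """Weight matrix W = V^T R V expressing functional eigenmodes in the
        structural eigenbasis (u_i = V w_i)."""
        if self.model is None:
            raise ValueError("no training data attached")
        V = self.model.structural_eig.eigenvectors
        return V.T @ self.rotation @ V

    def summary(self) -> str:
        lines = [
            "Individual spectral mapping results",
            "=" * 46,
            f"regions (n):            {self.n}",
            f"polynomial order (k):   {self.k}",
            f"rotation rank (m):      {self.rank_m}",
            f"fit residual ||.||_F^2: {self.fit_residual:.6e}",
        ]
        if self.model is not None:
            lines.append(f"in-sample ucorr:        {self.ucorr_insample():.6f}")
        lines.append("coefficients a_0..a_k (raw scale):")
        lines.append("  " + "  ".join(f"{a:.6g}" for a in self.params))
        return "\n".join(lines)


class IndividualSpectralMapping:
    """Per-subject structure-to-function mapping model.

    Parameters
    ----------
    structural : StructuralMatrix or array-like
        Symmetric non-negative adjacency matrix S of the structural graph.
    functional : FunctionalMatrix or array-like
        Symmetric functional correlation matrix F of the same dimension.
    """

    def __init__(self, structural, functional):
        S = _values(structural)
        F = _values(functional)
        if S.shape != F.shape:
            raise ValueError(f"dimension mismatch: S is {S.shape}, F is {F.shape}")
        self.structural = S
        self.functional = F
        self.n = S.shape[0]
        self._eig_s: Optional[EigenSystem] = None
        self._eig_f: Optional[EigenSystem] = None

    @classmethod
    def from_files(cls, structural_path, functional_path):
        from .io import read_matrix

        return cls(
            read_matrix(structural_path, "structural"),
            read_matrix(functional_path, "functional"),
        )

    @property
    def structural_eig(self) -> EigenSystem:
        if self._eig_s is None:
            self._eig_s = eigendecompose(self.structural)
        return self._eig_s

    @property
    def functional_eig(self) -> EigenSystem:
        if self._eig_f is None:
            self._eig_f = eigendecompose(self.functional)
        return self._eig_f

    def fit(self, k: int, rank: Optional[int] = None) -> IndividualMappingResults:
        """Closed-form fit of the order-k mapping.

        ``rank`` (m) restricts the number of freely aligned eigenmode pairs;
        ``rank=None`` (or n) gives the unconstrained Procrustes solution
        R* = U V^T.
        """
        if k < 0:
            raise ValueError("polynomial order k must be >= 0")
        if self.n < k + 1:
            raise ValueError(
                f"underdetermined design: n={self.n} < k+1={k + 1}"
            )
        m = self.n if rank is None else int(rank)
        lam = self.structural_eig.eigenvalues
        phi = self.functional_eig.eigenvalues
        if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(phi))):
            raise ValueError("non-finite spectra")
        poly = _fit_coefficients(lam, phi, k)
        U = self.functional_eig.eigenvectors
        V = self.structural_eig.eigenvectors
        R = _rank_constrained_rotation(U, V, m)
        fvals = poly(lam)
        B = R @ V
        Fhat = (B * fvals) @ B.T
        residual = float(np.sum((Fhat - self.functional) ** 2))
        return IndividualMappingResults(
            poly=poly,
            rotation=R,
            rank_m=m,
            n=self.n,
            k=k,
            fit_residual=residual,
            model=self,
        )


# ---------------------------------------------------------------------------
# functional wrappers (operation surface)
# ---------------------------------------------------------------------------

def fit_individual(S, F, k: int) -> IndividualMappingResults:
    """Closed-form per-subject fit (unconstrained rotation)."""
    return IndividualSpectralMapping(S, F).fit(k)


def fit_individual_rank_constrained(S, F, k: int, m: int) -> IndividualMappingResults:
    """Per-subject fit with only the top-m eigenmode pairs freely aligned."""
    return IndividualSpectralMapping(S, F).fit(k, rank=m)


def map_functional(model: IndividualMappingResults, S) -> np.ndarray:
    """Apply a fitted mapping to a structural matrix: F_hat = R f(S) R^T."""
    return model.predict(S)


def eigenmode_weights(
    model: IndividualMappingResults,
    structural_eig: EigenSystem,
    functional_eig: Optional[EigenSystem] = None,
) -> np.ndarray:
    """Weight matrix W = V^T R V with U = V W (functional eigenmodes as
    linear combinations of structural eigenmodes)."""
    V = structural_eig.eigenvectors
    if V.shape != model.rotation.shape:
        raise ValueError("eigensystem dimension does not match model")
    return V.T @ model.rotation @ V
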