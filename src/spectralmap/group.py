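"""Group (cohort-level) spectral mapping with a shared eigenmode basis.

Model
-----
For a cohort {(S_j, F_j)} of N subjects the group mapping predicts

    F_hat_j = Q g(Lambda_j) Q^T,   g(x) = c_0 + c_1 x + ... + c_k x^k,

where Lambda_j holds subject j's structural eigenvalues (descending) and Q
is a single orthogonal matrix of common functional eigenmodes shared by the
whole cohort; the subject's own structural eigenvectors are deliberately not
used.  Q and the shared coefficients c minimize the summed squared Frobenius
error sum_j ||Q g(Lambda_j) Q^T - F_j||_F^2 subject to Q Q^T = Q^T Q = I.

This is a joint-approximate-diagonalization problem and has no closed form;
it is solved by alternating minimization:

* c-step — with Q fixed, off-diagonal entries of Q^T F_j Q do not depend on
  c, so the minimization reduces exactly to a stacked (N n) x (k+1)
  Vandermonde least-squares fit of diag(Q^T F_j Q) against each subject's
  eigenvalues (on a cohort-wide conditioned scale).
* Q-step — with c fixed, Riemannian steepest descent on the orthogonal
  manifold: closed-form Euclidean gradient, projection to the tangent
  space, QR retraction, and backtracking (Armijo) line search, which
  guarantees a non-increasing objective.

The recorded objective trace is non-increasing by construction; iteration
stops on a relative decrease below ``tol`` or at ``max_iter`` (reported,
not silent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .spectral import PolynomialMap, eigendecompose, fix_eigenvector_signs

__all__ = [
    "Cohort",
    "GroupSpectralMapping",
    "GroupMappingResults",
    "fit_group",
    "map_group",
    "split_cohort",
]


def _values(X) -> np.ndarray:
    return np.asarray(getattr(X, "values", X), dtype=float)


@dataclass
class Cohort:
    """List of per-subject (structural, functional) matrix pairs, uniform n."""

    subjects: List[Tuple[object, object]]

    def __post_init__(self):
        if not self.subjects:
            raise ValueError("cohort must contain at least one subject")
        n = _values(self.subjects[0][0]).shape[0]
        for j, (S, F) in enumerate(self.subjects):
            Sv, Fv = _values(S), _values(F)
            if Sv.shape != (n, n) or Fv.shape != (n, n):
                raise ValueError(
                    f"subject {j}: shapes {Sv.shape}/{Fv.shape} differ from cohort n={n}"
                )
        self._n = n

    @property
    def n(self) -> int:
        return self._n

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def structural(self, j: int) -> np.ndarray:
        return _values(self.subjects[j][0])

    def functional(self, j: int) -> np.ndarray:
        return _values(self.subjects[j][1])

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)


@dataclass
class GroupMappingResults:
    """Fitted group mapping: common basis Q and shared coefficients c."""

    basis: np.ndarray
    poly: PolynomialMap
    n: int
    k: int
    objective_trace: List[float]
    n_subjects_train: int
    converged: bool = True
    model: Optional["GroupSpectralMapping"] = field(default=None, repr=False)

    def __post_init__(self):
        Q = np.asarray(self.basis, dtype=float)
        if Q.shape != (self.n, self.n):
            raise ValueError(f"basis has shape {Q.shape}, expected ({self.n}, {self.n})")
        err = float(np.abs(Q @ Q.T - np.eye(self.n)).max())
        if err > 1e-8:
            raise ValueError(f"basis is not orthogonal (max deviation {err:.2e})")
        tr = np.asarray(self.objective_trace, dtype=float)
        if tr.size > 1 and np.any(np.diff(tr) > 1e-12 * max(1.0, tr[0])):
            raise ValueError("objective trace is not non-increasing")
        self.basis = Q

    @property
    def params(self) -> np.ndarray:
        """Shared coefficients c_0..c_k on the raw eigenvalue scale."""
        return self.poly.raw_coefficients

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    def predict(self, S) -> np.ndarray:
        """F_hat = Q g(Lambda(S)) Q^T — uses only S's eigenvalues."""
        X = _values(S)
        if X.shape != (self.n, self.n):
            raise ValueError(f"structural matrix has shape {X.shape}, model has n={self.n}")
        lam = eigendecompose(X).eigenvalues
        g = self.poly(lam)
        Fhat = (self.basis * g) @ self.basis.T
        return (Fhat + Fhat.T) / 2.0

    def summary(self) -> str:
        lines = [
            "Group spectral mapping results",
            "=" * 46,
            f"regions (n):             {self.n}",
            f"polynomial order (k):    {self.k}",
            f"training subjects (N):   {self.n_subjects_train}",
            f"iterations:              {len(self.objective_trace) - 1}",
            f"converged:               {self.converged}",
            f"final objective:         {self.objective:.6e}",
            "coefficients c_0..c_k (raw scale):",
            "  " + "  ".join(f"{c:.6g}" for c in self.params),
        ]
        return "\n".join(lines)


def _qr_retract(Y: np.ndarray) -> np.ndarray:
    """QR-based retraction onto the orthogonal manifold (signs fixed)."""
    Q, r = np.linalg.qr(Y)
    d = np.sign(np.diag(r))
    d[d == 0] = 1.0
    return Q * d


class GroupSpectralMapping:
    """Cohort-level structure-to-function mapping model.

    Parameters
    ----------
    cohort : Cohort or sequence of (S, F) pairs
        Training subjects; all matrices must share the dimension n.
    """

    def __init__(self, cohort):
        if not isinstance(cohort, Cohort):
            cohort = Cohort(list(cohort))
        self.cohort = cohort
        self.n = cohort.n
        # per-subject spectra (descending) and functional matrices
        self._lams = [
            eigendecompose(cohort.structural(j)).eigenvalues
            for j in range(cohort.n_subjects)
        ]
        self._Fs = [cohort.functional(j) for j in range(cohort.n_subjects)]
        scale = max(float(np.abs(l).max()) for l in self._lams)
        self._scale = scale if scale > 0 else 1.0

    # -- objective pieces ---------------------------------------------------

    def _objective(self, Q: np.ndarray, gvals: Sequence[np.ndarray]) -> float:
        total = 0.0
        for g, F in zip(gvals, self._Fs):
            M = (Q * g) @ Q.T - F
            total += float(np.sum(M * M))
        return total

    def _fit_coefficients(self, Q: np.ndarray, k: int) -> PolynomialMap:
        """Exact c-step: stacked Vandermonde least squares of diag(Q^T F_j Q)."""
        rows = []
        targets = []
        for lam, F in zip(self._lams, self._Fs):
            rows.append(np.vander(lam / self._scale, N=k + 1, increasing=True))
            targets.append(np.einsum("ij,jk,ki->i", Q.T, F, Q))
        L = np.vstack(rows)
        phi = np.concatenate(targets)
        coeffs, *_ = np.linalg.lstsq(L, phi, rcond=None)
        return PolynomialMap(coeffs, eigenvalue_scale=self._scale)

    def _gradient(self, Q: np.ndarray, gvals: Sequence[np.ndarray]) -> np.ndarray:
        """Riemannian gradient of the objective at Q (tangent projection)."""
        G = np.zeros_like(Q)
        for g, F in zip(gvals, self._Fs):
            M = (Q * g) @ Q.T - F  # symmetric
            G += 4.0 * (M @ Q) * g
        sym = (Q.T @ G + G.T @ Q) / 2.0
        return G - Q @ sym

    # -- solver -------------------------------------------------------------

    def fit(
        self,
        k: int,
        max_iter: int = 500,
        tol: float = 1e-8,
        seed: Optional[int] = None,
        n_starts: int = 1,
    ) -> GroupMappingResults:
        """Alternating minimization for the group mapping.

        The default start is deterministic (eigenvectors of the cohort-mean
        functional matrix, descending); ``n_starts > 1`` adds seeded Haar
        random restarts and keeps the best objective.
        """
        if k < 0:
            raise ValueError("polynomial order k must be >= 0")
        if self.n < k + 1:
            raise ValueError(f"underdetermined design: n={self.n} < k+1={k + 1}")
        if max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if tol <= 0:
            raise ValueError("tol must be positive")
        starts = [self._warm_start()]
        if n_starts > 1:
            rng = np.random.default_rng(seed)
            for _ in range(n_starts - 1):
                A = rng.standard_normal((self.n, self.n))
                starts.append(_qr_retract(A))
        best: Optional[GroupMappingResults] = None
        for Q0 in starts:
            res = self._fit_single(Q0, k, max_iter, tol)
            if best is None or res.objective < best.objective:
                best = res
        return best

    def _warm_start(self) -> np.ndarray:
        Fbar = np.mean(self._Fs, axis=0)
        return eigendecompose(Fbar).eigenvectors

    def _fit_single(
        self, Q0: np.ndarray, k: int, max_iter: int, tol: float
    ) -> GroupMappingResults:
        Q = Q0.copy()
        poly = self._fit_coefficients(Q, k)
        gvals = [poly(lam) for lam in self._lams]
        obj = self._objective(Q, gvals)
        trace = [obj]
        alpha = 1e-2
        converged = False
        for _ in range(max_iter):
            # Q-step: projected steepest descent with backtracking
            G = self._gradient(Q, gvals)
            gnorm2 = float(np.sum(G * G))
            if gnorm2 > 0:
                step = alpha
                accepted = False
                for _bt in range(40):
                    Q_try = _qr_retract(Q - step * G)
                    obj_try = self._objective(Q_try, gvals)
                    if obj_try <= obj - 1e-4 * step * gnorm2:
                        accepted = True
                        break
                    step /= 2.0
                if accepted:
                    Q = Q_try
                    obj = obj_try
                    alpha = min(step * 2.0, 1.0)
            # c-step: exact minimizer given Q
            poly = self._fit_coefficients(Q, k)
            gvals = [poly(lam) for lam in self._lams]
            obj = min(obj, self._objective(Q, gvals))
            trace.append(obj)
            prev = trace[-2]
            rel = (prev - obj) / max(prev, 1e-300)
            if rel < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"group solver reached max_iter={max_iter} without relative "
                f"decrease below tol={tol:g}",
                RuntimeWarning,
                stacklevel=3,
            )
        return GroupMappingResults(
            basis=Q,
            poly=poly,
            n=self.n,
            k=k,
            objective_trace=trace,
            n_subjects_train=self.cohort.n_subjects,
            converged=converged,
            model=self,
        )


# ---------------------------------------------------------------------------
# functional wrappers (operation surface)
# ---------------------------------------------------------------------------

def fit_group(
    cohort,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: Optional[int] = None,
    n_starts: int = 1,
) -> GroupMappingResults:
    """Fit the shared-basis group mapping on a cohort."""
    return GroupSpectralMapping(cohort).fit(
        k, max_iter=max_iter, tol=tol, seed=seed, n_starts=n_starts
    )


def map_group(model: GroupMappingResults, S) -> np.ndarray:
    """Apply a fitted group mapping to a structural matrix."""
    return model.predict(S)


def split_cohort(cohort, fraction: float, seed: int) -> Tuple[Cohort, Cohort]:
    """Deterministic subject-level partition into train/validate cohorts.

    Sizes are ceil(f N) and the remainder; the partition is disjoint,
    exhaustive and a pure function of ``seed``.
    """
    if not isinstance(cohort, Cohort):
        cohort = Cohort(list(cohort))
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    N = cohort.n_subjects
    if N < 2:
        raise ValueError("need at least 2 subjects to split")
    n_train = int(np.ceil(fraction * N))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    train_idx = np.sort(perm[:n_train])
    val_idx = np.sort(perm[n_train:])
    train = Cohort([cohort.subjects[i] for i in train_idx])
    validate = Cohort([cohort.subjects[i] for i in val_idx])
    return train, validate
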