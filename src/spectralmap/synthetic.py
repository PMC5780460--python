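"""Synthetic connectomes, planted mappings, cohorts, and BOLD-like series.

Every generator is a pure function of its specification and seed, so the
whole estimation and evaluation surface can be exercised without any data
download.  The generators emulate the *statistical* structure the method
relies on — weighted symmetric graphs, functional matrices that are exact
(or noisy) images of a planted polynomial-plus-rotation mapping, cohorts
with controllable cross-subject spectral similarity, and stationary
autoregressive time series whose correlation structure follows
walk-weighted structural proximity.  They do not attempt hemodynamic or
neural-mass realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .io import BoldSeries, FunctionalMatrix, StructuralMatrix, normalize_structural
from .spectral import PolynomialMap, eigendecompose
from .individual import IndividualMappingResults
from .group import Cohort, GroupMappingResults

__all__ = [
    "SyntheticSpec",
    "make_structural",
    "make_planted_pair",
    "make_cohort",
    "make_bold_series",
    "haar_orthogonal",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic data regime.

    Defaults describe a mid-sized parcellation with moderately dense
    connectivity: n = 60 parcels, edge density 0.3, uniform weights,
    planted polynomial of order 3, noiseless planted mappings.
    """

    n: int = 60
    density: float = 0.3
    weight_law: str = "uniform"  # or "lognormal"
    true_k: int = 3
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2 parcels")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must lie in (0, 1]")
        if self.weight_law not in ("uniform", "lognormal"):
            raise ValueError("weight_law must be 'uniform' or 'lognormal'")
        if self.true_k < 0:
            raise ValueError("true_k must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def haar_orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform random orthogonal matrix (QR of a Gaussian, signs fixed)."""
    A = rng.standard_normal((n, n))
    Q, r = np.linalg.qr(A)
    d = np.sign(np.diag(r))
    d[d == 0] = 1.0
    return Q * d


def _random_graph(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < spec.density
    if spec.weight_law == "uniform":
        w = rng.uniform(0.1, 1.0, size=len(iu[0]))
    else:
        w = rng.lognormal(mean=0.0, sigma=1.0, size=len(iu[0]))
    X = np.zeros((n, n))
    X[iu] = np.where(mask, w, 0.0)
    X = X + X.T
    return X


def make_structural(spec: SyntheticSpec, seed: Optional[int] = None) -> StructuralMatrix:
    """Erdos-Renyi-style weighted symmetric graph, max-normalized, zero diagonal."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    X = _random_graph(spec, rng)
    if X.max() <= 0:
        raise ValueError("generated graph has no edges; increase density or n")
    return normalize_structural(StructuralMatrix(X))


def _planted_polynomial(rng: np.random.Generator, k: int, scale: float) -> PolynomialMap:
    """Polynomial strictly increasing on the conditioned spectrum [-1, 1].

    Coefficients on the conditioned scale t = lambda/scale: higher-order
    coefficients are drawn in (0, 1) and the linear coefficient is set above
    sum_i i*c_i, so f'(t) > 0 on [-1, 1] holds by construction.
    """
    c = np.zeros(k + 1)
    c[0] = rng.uniform(-0.5, 0.5)
    if k >= 1:
        if k >= 2:
            c[2:] = rng.uniform(0.05, 0.5, size=k - 1)
        c[1] = float(np.sum(np.arange(2, k + 1) * c[2:])) + rng.uniform(0.5, 1.5)
    poly = PolynomialMap(c, eigenvalue_scale=scale)
    # defensive check of the identifiability condition (cannot fire by
    # construction, but the invariant is load-bearing for exact recovery)
    t = np.linspace(-1.0, 1.0, 201)
    deriv = np.polyval(np.polyder(c[::-1]), t) if k >= 1 else np.zeros_like(t)
    if k >= 1 and np.any(deriv <= 0):
        raise RuntimeError("planted polynomial is not strictly increasing")
    return poly


def make_planted_pair(
    spec: SyntheticSpec,
    seed: Optional[int] = None,
    rotation: Optional[np.ndarray] = None,
) -> Tuple[StructuralMatrix, FunctionalMatrix, IndividualMappingResults]:
    """Structural matrix plus a functional matrix generated by a planted mapping.

    F = R0 (sum_i a_i S^i) R0^T + noise, with R0 Haar-orthogonal and the
    polynomial strictly increasing on the spectrum of S (which makes the
    descending eigenvalue pairings of S and F coincide, the identifiability
    condition for exact recovery at noise_sigma = 0).  The returned
    ground-truth mapping carries the planted coefficients and rotation;
    the functional matrix is rescaled to [-1, 1] and the coefficients with
    it, so ground truth remains exact.

    ``rotation`` overrides the Haar draw of R0 (e.g. the identity, which
    makes F share S's eigenvectors).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    S = make_structural(spec, seed=int(rng.integers(2**31)))
    eig = eigendecompose(S.values)
    scale = float(np.abs(eig.eigenvalues).max())
    poly = _planted_polynomial(rng, spec.true_k, scale)
    R0 = haar_orthogonal(spec.n, rng) if rotation is None else np.asarray(rotation, float)
    B = R0 @ eig.eigenvectors
    F = (B * poly(eig.eigenvalues)) @ B.T
    F = (F + F.T) / 2.0
    if spec.noise_sigma > 0:
        E = rng.standard_normal((spec.n, spec.n)) * spec.noise_sigma
        F = F + (E + E.T) / 2.0
    fmax = float(np.abs(F).max())
    if fmax == 0:
        raise ValueError("degenerate planted functional matrix (all zero)")
    F = F / fmax
    poly = PolynomialMap(poly.coefficients / fmax, eigenvalue_scale=scale)
    truth = IndividualMappingResults(
        poly=poly,
        rotation=R0,
        rank_m=spec.n,
        n=spec.n,
        k=spec.true_k,
        fit_residual=0.0,
    )
    return S, FunctionalMatrix(F), truth


def make_cohort(
    spec: SyntheticSpec,
    N: int,
    heterogeneity: float,
    seed: Optional[int] = None,
) -> Tuple[Cohort, dict]:
    """Cohort of N subjects with controllable cross-subject similarity.

    Subjects share a base structural graph perturbed multiplicatively per
    subject (entrywise uniform +-30%), giving similar but distinct spectra,
    as observed across real subjects.  ``heterogeneity`` in [0, 1]
    interpolates the functional eigenmode basis between a single shared
    orthogonal basis Q0 (heterogeneity = 0: exact planted *group* model
    F_j = Q0 g(Lambda_j) Q0^T with shared coefficients) and fully
    independent Haar bases per subject (heterogeneity = 1: independent
    planted *individual* mappings).

    Returns the cohort and a ``truth`` dict with the planted group model
    (``"group"``, only at heterogeneity 0) and the per-subject individual
    mappings (``"individual"``, always defined since any basis/polynomial
    pair is an individual mapping).
    """
    if N < 1:
        raise ValueError("need N >= 1 subjects")
    if not (0.0 <= heterogeneity <= 1.0):
        raise ValueError("heterogeneity must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    base = make_structural(spec, seed=int(rng.integers(2**31)))
    h = float(heterogeneity)
    n = spec.n
    Q0 = haar_orthogonal(n, rng)
    # shared coefficients on a provisional scale; rescaled after spectra known
    Ss: List[StructuralMatrix] = []
    eigs = []
    for _ in range(N):
        D = rng.uniform(-0.3, 0.3, size=(n, n))
        D = np.triu(D, k=1)
        D = D + D.T
        X = base.values * (1.0 + D)
        Sj = normalize_structural(StructuralMatrix(np.clip(X, 0.0, None)))
        Ss.append(Sj)
        eigs.append(eigendecompose(Sj.values))
    scale = max(float(np.abs(e.eigenvalues).max()) for e in eigs)
    c0_poly = _planted_polynomial(rng, spec.true_k, scale)
    subjects = []
    indiv_truth: List[IndividualMappingResults] = []
    Fraw = []
    bases = []
    polys = []
    for j in range(N):
        if h == 0.0:
            Bj = Q0
            poly_j = c0_poly
        else:
            Oj = haar_orthogonal(n, rng)
            M = (1.0 - h) * Q0 + h * Oj
            Q, r = np.linalg.qr(M)
            d = np.sign(np.diag(r))
            d[d == 0] = 1.0
            Bj = Q * d
            cj = _planted_polynomial(rng, spec.true_k, scale)
            poly_j = PolynomialMap(
                (1.0 - h) * c0_poly.coefficients + h * cj.coefficients, scale
            )
        g = poly_j(eigs[j].eigenvalues)
        Fj = (Bj * g) @ Bj.T
        Fj = (Fj + Fj.T) / 2.0
        if spec.noise_sigma > 0:
            E = rng.standard_normal((n, n)) * spec.noise_sigma
            Fj = Fj + (E + E.T) / 2.0
        Fraw.append(Fj)
        bases.append(Bj)
        polys.append(poly_j)
    # one cohort-wide rescale keeps shared coefficients shared
    fmax = max(float(np.abs(F).max()) for F in Fraw)
    if fmax == 0:
        raise ValueError("degenerate planted cohort (all-zero functional matrices)")
    for j in range(N):
        Fj = FunctionalMatrix(Fraw[j] / fmax)
        subjects.append((Ss[j], Fj))
        poly_j = PolynomialMap(polys[j].coefficients / fmax, scale)
        Rj = bases[j] @ eigs[j].eigenvectors.T
        indiv_truth.append(
            IndividualMappingResults(
                poly=poly_j,
                rotation=Rj,
                rank_m=n,
                n=n,
                k=spec.true_k,
                fit_residual=0.0,
            )
        )
    truth: dict = {"individual": indiv_truth, "group": None}
    if h == 0.0:
        truth["group"] = GroupMappingResults(
            basis=Q0,
            poly=PolynomialMap(c0_poly.coefficients / fmax, scale),
            n=n,
            k=spec.true_k,
            objective_trace=[0.0],
            n_subjects_train=N,
        )
    return Cohort(subjects), truth


def make_bold_series(
    S,
    L_samples: int,
    coupling: float,
    seed: int,
    burn_in: int = 200,
) -> BoldSeries:
    """Stationary first-order vector autoregression driven by the structural graph.

    x_t = A x_{t-1} + eps_t with A proportional to S, rescaled so that the
    spectral radius of A equals ``coupling`` (< 1, hence stationary; larger
    values give stronger, more heterogeneous correlations).  The population
    covariance solves the discrete Lyapunov equation and expands as
    sum_k A^k (A^k)^T — an increasing function of walk-weighted structural
    proximity; coupling = 0 gives uncorrelated white noise.  Bandpass
    filtering and hemodynamics are not emulated — the contract is the
    correlation structure only.
    """
    if L_samples < 8:
        raise ValueError("need at least 8 time samples")
    if not (0.0 <= coupling < 1.0):
        raise ValueError("coupling must lie in [0, 1) for a stable AR(1)")
    X = np.asarray(getattr(S, "values", S), dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    if coupling > 0:
        radius = float(np.abs(np.linalg.eigvalsh(X)).max())
        if radius == 0:
            raise ValueError("structural matrix has zero spectral radius")
        A = (coupling / radius) * X
    else:
        A = np.zeros((n, n))
    out = np.empty((n, L_samples))
    x = rng.standard_normal(n)
    for t in range(burn_in):
        x = A @ x + rng.standard_normal(n)
    for t in range(L_samples):
        x = A @ x + rng.standard_normal(n)
        out[:, t] = x
    return BoldSeries(out)
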