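"""Evaluation toolkit: sample splitting, stability sweeps, perturbation
robustness, null-model swap analyses, and cross-subject spectral
diagnostics.

All Monte-Carlo procedures take explicit seeds and are deterministic given
them.  Quality is measured throughout with :func:`spectralmap.ucorr`, the
Pearson correlation of strict upper-triangular entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import BoldSeries, FunctionalMatrix, StructuralMatrix
from .spectral import correlation_matrix, eigendecompose, matrix_polynomial, ucorr
from .individual import IndividualMappingResults, IndividualSpectralMapping
from .group import Cohort

__all__ = [
    "SplitPair",
    "PerturbationSpec",
    "NullModelReport",
    "split_time_series",
    "sweep_order",
    "perturb_structural",
    "perturbation_quality",
    "null_model_report",
    "spectral_similarity",
]


def _values(X) -> np.ndarray:
    return np.asarray(getattr(X, "values", X), dtype=float)


@dataclass
class SplitPair:
    """In/out-of-sample functional matrices from one time-sample split.

    One index set of size floor(L/2) is drawn uniformly without replacement
    and shared across all regions (inter-regional correlation requires
    temporally aligned samples); the complement forms the second set.
    """

    in_sample: FunctionalMatrix
    out_sample: FunctionalMatrix
    in_indices: np.ndarray
    out_indices: np.ndarray
    seed: int

    def __post_init__(self):
        a = set(self.in_indices.tolist())
        b = set(self.out_indices.tolist())
        if a & b:
            raise ValueError("split index sets are not disjoint")


def split_time_series(ts: BoldSeries, seed: int) -> SplitPair:
    """Random half-split of time samples into in/out-of-sample matrices."""
    if not isinstance(ts, BoldSeries):
        ts = BoldSeries(ts)
    L = ts.n_samples
    if L < 8:
        raise ValueError("need at least 8 time samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(L)
    half = L // 2
    idx1 = np.sort(perm[:half])
    idx2 = np.sort(perm[half:])
    F1 = correlation_matrix(BoldSeries(ts.signals[:, idx1]))
    F2 = correlation_matrix(BoldSeries(ts.signals[:, idx2]))
    return SplitPair(
        in_sample=F1, out_sample=F2, in_indices=idx1, out_indices=idx2, seed=seed
    )


def sweep_order(
    S,
    split: SplitPair,
    k_values: Iterable[int],
    m: Optional[int] = None,
) -> pd.DataFrame:
    """Fit on the in-sample matrix for each order k; report in/out quality.

    Returns a tidy table with columns ``k``, ``ucorr_in``, ``ucorr_out``.
    Degenerate cases (e.g. k = 0, where the mapped matrix is a multiple of
    the identity and its triangle is constant) are reported as NaN so that
    sweeps complete.
    """
    model = IndividualSpectralMapping(S, split.in_sample)
    records = []
    iu = np.triu_indices(model.n, k=1)
    for k in sorted(set(int(k) for k in k_values)):
        res = model.fit(k, rank=m)
        Fhat = res.fittedvalues
        tri = Fhat[iu]
        # constant triangle (e.g. k=0: F_hat is a multiple of I up to
        # rounding) -> flagged NaN instead of correlating rounding noise
        if tri.std() <= 1e-10 * max(float(np.abs(Fhat).max()), 1e-300):
            ui = uo = float("nan")
        else:
            try:
                ui = ucorr(Fhat, split.in_sample)
            except ValueError:
                ui = float("nan")
            try:
                uo = ucorr(Fhat, split.out_sample)
            except ValueError:
                uo = float("nan")
        records.append({"k": k, "ucorr_in": ui, "ucorr_out": uo})
    return pd.DataFrame.from_records(records)


@dataclass
class PerturbationSpec:
    """Symmetric multiplicative perturbation draw: entries of Delta are
    uniform(-rho, rho) on the upper triangle, mirrored below."""

    rho: float
    seed: int
    delta: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.delta, dtype=float)
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if float(np.abs(D - D.T).max()) > 0:
            raise ValueError("delta must be exactly symmetric")
        if D.size and float(np.abs(D).max()) > self.rho:
            raise ValueError("delta entries exceed the stated half-width rho")
        self.delta = D


def perturb_structural(
    S, rho: float, seed: int
) -> Tuple[StructuralMatrix, PerturbationSpec]:
    """Multiplicative noise model: [S_pert]_ij = (1 + Delta_ij) [S]_ij.

    Zero entries stay zero (the structural sparsity pattern is preserved)
    and the expected perturbation magnitude is proportional to the entry.
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    X = _values(S)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    D = np.zeros((n, n))
    iu = np.triu_indices(n, k=0)
    D[iu] = rng.uniform(-rho, rho, size=len(iu[0]))
    D = np.triu(D) + np.triu(D, k=1).T
    pert = X * (1.0 + D)
    pert = np.clip(pert, 0.0, None)  # rho <= 1 never triggers this
    labels = getattr(S, "region_labels", None)
    return StructuralMatrix(pert, region_labels=labels), PerturbationSpec(rho, seed, D)


def perturbation_quality(
    model: IndividualMappingResults, S, rho: float, seed: int
) -> float:
    """ucorr between the mapped matrix and its perturbed counterpart.

    F_check applies the *original* fitted parameters (a*, R*) to the
    perturbed structural matrix: F_check = R* (sum_i a_i* S_pert^i) R*^T.
    """
    Fhat = model.predict(S)
    S_pert, _ = perturb_structural(S, rho, seed)
    if rho == 0:
        return 1.0
    Om = matrix_polynomial(S_pert.values, model.poly)
    Fcheck = model.rotation @ Om @ model.rotation.T
    return ucorr(Fhat, Fcheck)


@dataclass
class NullModelReport:
    """ucorr tables for the six matrix/parameter-swap families.

    Families (i, j index subjects; F_hat_i^j is subject i's fitted mapping
    applied to subject j's structural matrix):

    - ``F_S_same``:        ucorr(F_i, S_i), N values
    - ``F_S_cross``:       ucorr(F_i, S_j), i != j, N(N-1) values
    - ``F_F_cross``:       ucorr(F_i, F_j), i < j, N(N-1)/2 values
    - ``S_S_cross``:       ucorr(S_i, S_j), i < j, N(N-1)/2 values
    - ``Fhat_cross_Fi``:   ucorr(F_hat_i^j, F_i), i != j, N(N-1) values
    - ``Fhat_cross_Fj``:   ucorr(F_hat_i^j, F_j), i != j, N(N-1) values
    - ``Fhat_self``:       ucorr(F_hat_i^i, F_i), N values (reference)
    """

    tables: Dict[str, np.ndarray]

    def __post_init__(self):
        for name, arr in self.tables.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size and (arr.min() < -1 - 1e-12 or arr.max() > 1 + 1e-12):
                raise ValueError(f"family {name}: correlations outside [-1, 1]")
            self.tables[name] = arr

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.tables.items():
            rows.append(
                {
                    "family": name,
                    "count": arr.size,
                    "mean": float(np.mean(arr)),
                    "std": float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0,
                    "median": float(np.median(arr)),
                }
            )
        return pd.DataFrame.from_records(rows).set_index("family")


def null_model_report(
    cohort, models: Sequence[IndividualMappingResults]
) -> NullModelReport:
    """Matrix- and parameter-swap null comparisons across a cohort.

    ``models[i]`` must be the individual mapping fitted on cohort subject i.
    """
    if not isinstance(cohort, Cohort):
        cohort = Cohort(list(cohort))
    N = cohort.n_subjects
    if len(models) != N:
        raise ValueError(f"{len(models)} models for {N} subjects")
    Ss = [cohort.structural(j) for j in range(N)]
    Fs = [cohort.functional(j) for j in range(N)]
    for i, mod in enumerate(models):
        if mod.n != cohort.n:
            raise ValueError(f"model {i} has n={mod.n}, cohort has n={cohort.n}")
    Fhat = {}
    for i in range(N):
        for j in range(N):
            Fhat[i, j] = models[i].predict(Ss[j])
    F_S_same = np.array([ucorr(Fs[i], Ss[i]) for i in range(N)])
    F_S_cross = np.array(
        [ucorr(Fs[i], Ss[j]) for i in range(N) for j in range(N) if j != i]
    )
    F_F_cross = np.array(
        [ucorr(Fs[i], Fs[j]) for i in range(N) for j in range(i + 1, N)]
    )
    S_S_cross = np.array(
        [ucorr(Ss[i], Ss[j]) for i in range(N) for j in range(i + 1, N)]
    )
    Fhat_cross_Fi = np.array(
        [ucorr(Fhat[i, j], Fs[i]) for i in range(N) for j in range(N) if j != i]
    )
    Fhat_cross_Fj = np.array(
        [ucorr(Fhat[i, j], Fs[j]) for i in range(N) for j in range(N) if j != i]
    )
    Fhat_self = np.array([ucorr(Fhat[i, i], Fs[i]) for i in range(N)])
    return NullModelReport(
        tables={
            "F_S_same": F_S_same,
            "F_S_cross": F_S_cross,
            "F_F_cross": F_F_cross,
            "S_S_cross": S_S_cross,
            "Fhat_cross_Fi": Fhat_cross_Fi,
            "Fhat_cross_Fj": Fhat_cross_Fj,
            "Fhat_self": Fhat_self,
        }
    )


def spectral_similarity(cohort) -> Dict[str, pd.DataFrame]:
    """Cross-subject spectral diagnostics.

    Returns
    -------
    dict with two tables:

    - ``eigenvalues``: per-rank quartiles (q1, median, q3, mean) of the
      descending-ordered eigenvalues across subjects, for both modalities.
    - ``eigenvector_correlations``: all-pairs absolute Pearson correlations
      between subjects' first and second eigenvectors (sign convention
      applied, absolute value taken since eigenvector sign is arbitrary);
      l(l-1)/2 pairs per modality/rank.
    """
    if not isinstance(cohort, Cohort):
        cohort = Cohort(list(cohort))
    l = cohort.n_subjects
    if l < 2:
        raise ValueError("spectral similarity requires at least 2 subjects")
    eigs = {
        "structural": [eigendecompose(cohort.structural(j)) for j in range(l)],
        "functional": [eigendecompose(cohort.functional(j)) for j in range(l)],
    }
    rows = []
    for modality, systems in eigs.items():
        vals = np.stack([e.eigenvalues for e in systems])  # subjects x rank
        for r in range(cohort.n):
            col = vals[:, r]
            rows.append(
                {
                    "modality": modality,
                    "rank": r + 1,
                    "q1": float(np.percentile(col, 25)),
                    "median": float(np.median(col)),
                    "q3": float(np.percentile(col, 75)),
                    "mean": float(np.mean(col)),
                }
            )
    eig_table = pd.DataFrame.from_records(rows)
    corr_rows = []
    for modality, systems in eigs.items():
        for rank in (1, 2):
            vecs = np.stack([e.eigenvectors[:, rank - 1] for e in systems])
            for i in range(l):
                for j in range(i + 1, l):
                    r = float(np.corrcoef(vecs[i], vecs[j])[0, 1])
                    corr_rows.append(
                        {
                            "modality": modality,
                            "rank": rank,
                            "subject_i": i,
                            "subject_j": j,
                            "abs_correlation": abs(r),
                        }
                    )
    corr_table = pd.DataFrame.from_records(corr_rows)
    return {"eigenvalues": eig_table, "eigenvector_correlations": corr_table}
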