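"""Connectivity-matrix and model I/O with boundary invariant enforcement.

Matrices travel as dense delimited text (comma or whitespace, autodetected),
one row per region, optionally with a header row of region labels mirrored
in a first label column.  Fitted mappings are stored as self-describing JSON
whose floats round-trip exactly (Python ``repr`` precision, >= 17 significant
digits).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StructuralMatrix",
    "FunctionalMatrix",
    "BoldSeries",
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "normalize_structural",
    "read_mapping",
    "write_mapping",
]

#: relative tolerance above which an asymmetric input is rejected instead of
#: symmetrized; matrices are expected to be symmetrized upstream, so large
#: corrections would mask data errors.
ASYMMETRY_RTOL = 1e-8


def _as_square_float(values) -> np.ndarray:
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains NaN or infinite entries")
    return X


def _symmetrize(X: np.ndarray, what: str) -> np.ndarray:
    scale = max(1.0, float(np.abs(X).max())) if X.size else 1.0
    asym = float(np.abs(X - X.T).max()) if X.size else 0.0
    if asym > ASYMMETRY_RTOL * scale:
        raise ValueError(
            f"{what} matrix asymmetry {asym:.3e} exceeds tolerance "
            f"{ASYMMETRY_RTOL:.0e} (relative); refusing to symmetrize"
        )
    return (X + X.T) / 2.0


@dataclass
class StructuralMatrix:
    """Symmetric non-negative weighted adjacency of the structural graph.

    Entries are dimensionless streamline-derived weights between brain
    parcels.  ``normalized`` indicates the matrix has been divided by its
    overall maximum weight (max entry exactly 1).
    """

    values: np.ndarray
    region_labels: Optional[Sequence[str]] = None
    normalized: bool = False

    def __post_init__(self):
        X = _as_square_float(self.values)
        X = _symmetrize(X, "structural")
        if X.size and X.min() < 0:
            raise ValueError("structural matrix has negative entries")
        if self.normalized and X.size and not np.isclose(X.max(), 1.0):
            raise ValueError("normalized flag set but max entry is not 1")
        if self.region_labels is not None and len(self.region_labels) != X.shape[0]:
            raise ValueError("region_labels length does not match matrix size")
        self.values = X

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class FunctionalMatrix:
    """Symmetric matrix of Pearson correlations between regional signals."""

    values: np.ndarray
    region_labels: Optional[Sequence[str]] = None

    def __post_init__(self):
        X = _as_square_float(self.values)
        X = _symmetrize(X, "functional")
        if X.size and (X.min() < -1 - 1e-12 or X.max() > 1 + 1e-12):
            raise ValueError("functional matrix entries must lie in [-1, 1]")
        if self.region_labels is not None and len(self.region_labels) != X.shape[0]:
            raise ValueError("region_labels length does not match matrix size")
        self.values = np.clip(X, -1.0, 1.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class BoldSeries:
    """Region x time-sample signal array (BOLD-like, arbitrary units)."""

    signals: np.ndarray
    sampling_interval: Optional[float] = None

    def __post_init__(self):
        X = np.asarray(self.signals, dtype=float)
        if X.ndim != 2:
            raise ValueError("signals must be a 2-D (regions x samples) array")
        if X.shape[0] < 2 or X.shape[1] < 4:
            raise ValueError("need at least 2 regions and 4 time samples")
        if not np.all(np.isfinite(X)):
            raise ValueError("signals contain NaN or infinite values")
        if np.any(X.std(axis=1) == 0):
            raise ValueError("at least one region has zero variance")
        self.signals = X

    @property
    def n_regions(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


@dataclass
class RunConfig:
    """Run parameters shared by the fitting and evaluation entry points."""

    k: int = 8
    m: Optional[int] = None  # rotation rank; None means full rank n
    seed: int = 0
    split_fraction: float = 0.5
    max_iter: int = 500
    tol: float = 1e-8

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("polynomial order k must be >= 0")
        if self.m is not None and self.m < 1:
            raise ValueError("rotation rank m must be >= 1")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


# ---------------------------------------------------------------------------
# matrix files
# ---------------------------------------------------------------------------

def _tokenize(line: str) -> list[str]:
    line = line.strip()
    if "," in line:
        return [t.strip() for t in line.split(",")]
    return line.split()


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_matrix(path, kind: str):
    """Read a dense connectivity matrix from delimited text.

    Parameters
    ----------
    path : path-like
        Comma- or whitespace-delimited dense numeric text; an optional
        header row of region labels may be present, mirrored in an optional
        first label column.
    kind : {"structural", "functional"}
        Selects the returned container and the invariants enforced
        (non-negativity for structural, [-1, 1] range for functional).
    """
    if kind not in ("structural", "functional"):
        raise ValueError(f"kind must be 'structural' or 'functional', got {kind!r}")
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    rows = [_tokenize(ln) for ln in lines]
    labels = None
    if not all(_is_number(t) for t in rows[0]):
        labels = [t for t in rows[0] if t]
        rows = rows[1:]
        if rows and not _is_number(rows[0][0]):
            # header mirrored in a first label column
            rows = [r[1:] for r in rows]
    try:
        X = np.array([[float(t) for t in r] for r in rows], dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric entry in matrix body") from exc
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError(f"{path}: matrix is not square (shape {X.shape})")
    if labels is not None and len(labels) != X.shape[0]:
        raise ValueError(f"{path}: {len(labels)} labels for {X.shape[0]} rows")
    if kind == "structural":
        return StructuralMatrix(X, region_labels=labels)
    return FunctionalMatrix(X, region_labels=labels)


def write_matrix(matrix, path, delimiter: str = ",") -> None:
    """Write a matrix container (or bare array) as dense delimited text."""
    values = getattr(matrix, "values", matrix)
    labels = getattr(matrix, "region_labels", None)
    X = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        if labels is not None:
            fh.write(delimiter.join(str(l) for l in labels) + "\n")
        for row in X:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def normalize_structural(S: StructuralMatrix) -> StructuralMatrix:
    """Divide all entries by the overall maximum weight (max entry -> 1)."""
    mx = float(S.values.max()) if S.values.size else 0.0
    if mx <= 0:
        raise ValueError("cannot normalize an all-zero structural matrix")
    return StructuralMatrix(
        S.values / mx, region_labels=S.region_labels, normalized=True
    )


def read_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file (unknown keys rejected)."""
    import yaml

    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: config must be a mapping of RunConfig fields")
    allowed = {"k", "m", "seed", "split_fraction", "max_iter", "tol"}
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
    return RunConfig(**payload)


def read_series(path) -> BoldSeries:
    """Read a region x time-sample signal array from delimited text."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty series file")
    try:
        X = np.array([[float(t) for t in _tokenize(ln)] for ln in lines], dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric entry in series file") from exc
    return BoldSeries(X)


def write_series(ts: BoldSeries, path, delimiter: str = ",") -> None:
    """Write a BOLD-like series as dense delimited text, one row per region."""
    X = np.asarray(getattr(ts, "signals", ts), dtype=float)
    with open(path, "w") as fh:
        for row in X:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# model files
# ---------------------------------------------------------------------------

def write_mapping(model, path, provenance: Optional[dict] = None) -> None:
    """Serialize a fitted individual or group mapping to JSON.

    Floats are written at full ``repr`` precision so that
    ``read_mapping(write_mapping(m))`` reproduces every field exactly.
    """
    from .individual import IndividualMappingResults
    from .group import GroupMappingResults

    if isinstance(model, IndividualMappingResults):
        payload = {
            "type": "individual",
            "n": int(model.n),
            "k": int(model.k),
            "rank_m": int(model.rank_m),
            "coefficients": [float(c) for c in model.poly.coefficients],
            "eigenvalue_scale": float(model.poly.eigenvalue_scale),
            "rotation": model.rotation.tolist(),
            "fit_residual": float(model.fit_residual),
        }
    elif isinstance(model, GroupMappingResults):
        payload = {
            "type": "group",
            "n": int(model.n),
            "k": int(model.k),
            "coefficients": [float(c) for c in model.poly.coefficients],
            "eigenvalue_scale": float(model.poly.eigenvalue_scale),
            "basis": model.basis.tolist(),
            "objective_trace": [float(v) for v in model.objective_trace],
            "n_subjects_train": int(model.n_subjects_train),
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    if not all(np.isfinite(payload["coefficients"])):
        raise ValueError("model coefficients are not finite")
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=1))


def read_mapping(path):
    """Load a mapping written by :func:`write_mapping`."""
    from .spectral import PolynomialMap
    from .individual import IndividualMappingResults
    from .group import GroupMappingResults

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed model file") from exc
    kind = payload.get("type")
    n, k = int(payload["n"]), int(payload["k"])
    coeffs = np.asarray(payload["coefficients"], dtype=float)
    if coeffs.shape != (k + 1,):
        raise ValueError(f"{path}: expected {k + 1} coefficients, got {coeffs.shape}")
    poly = PolynomialMap(coeffs, float(payload["eigenvalue_scale"]))
    if kind == "individual":
        R = np.asarray(payload["rotation"], dtype=float)
        if R.shape != (n, n):
            raise ValueError(f"{path}: rotation has shape {R.shape}, expected ({n}, {n})")
        return IndividualMappingResults(
            poly=poly,
            rotation=R,
            rank_m=int(payload["rank_m"]),
            n=n,
            k=k,
            fit_residual=float(payload["fit_residual"]),
        )
    if kind == "group":
        Q = np.asarray(payload["basis"], dtype=float)
        if Q.shape != (n, n):
            raise ValueError(f"{path}: basis has shape {Q.shape}, expected ({n}, {n})")
        return GroupMappingResults(
            basis=Q,
            poly=poly,
            n=n,
            k=k,
            objective_trace=list(map(float, payload["objective_trace"])),
            n_subjects_train=int(payload["n_subjects_train"]),
        )
    raise ValueError(f"{path}: unknown model type {kind!r}")
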