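"""Connectome matrix I/O, validation, vectorization and normalization.

A structural connectome is stored on disk as a plain-text ``n x n`` numeric
matrix (comma- or whitespace-delimited), the dialect emitted by standard
tractography connectome builders.  In memory it is a symmetric, non-negative,
zero-diagonal :class:`numpy.ndarray` wrapped in :class:`ConnectomeMatrix`.

The canonical feature representation is the strict upper triangle flattened
row-major: pairs ``(i, j)`` with ``i < j`` ordered by ``i`` then ``j``.  For
the 84-region Desikan-Killiany parcellation this gives 3486 edge values per
participant.  The ordering is part of the file-format contract — saliency
scores are only comparable across runs because it never changes.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("connectomlp")

#: Relative tolerance under which an asymmetric input matrix is repaired by
#: averaging; beyond it the file is considered corrupt.
ASYMMETRY_RTOL = 1e-6

VALID_HEMISPHERES = frozenset({"L", "R", "M"})


class ConnectomeError(ValueError):
    """Raised for invalid connectome files or degenerate matrices."""


# ---------------------------------------------------------------------------
# Node table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeTable:
    """Atlas lookup table: region names and hemisphere codes, 0-based.

    Hemisphere codes are ``L``/``R`` for lateralised regions and ``M`` for
    midline structures (``M`` regions never count toward cross-hemisphere
    edges).
    """

    names: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.hemispheres):
            raise ValueError("names and hemispheres must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("node names must be unique")
        bad = set(self.hemispheres) - VALID_HEMISPHERES
        if bad:
            raise ValueError(f"invalid hemisphere codes: {sorted(bad)}")

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown node name: {name!r}") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NodeTable":
        """Read a node table from TSV with columns ``index name hemisphere``."""
        df = pd.read_csv(path, sep="\t")
        for col in ("index", "name", "hemisphere"):
            if col not in df.columns:
                raise ValueError(f"node table missing column {col!r}")
        idx = df["index"].to_numpy(dtype=int)
        if not np.array_equal(idx, np.arange(len(df))):
            raise ValueError("node indices must be exactly 0..n-1 in order")
        return cls(tuple(df["name"]), tuple(df["hemisphere"]))

    @classmethod
    def default(cls) -> "NodeTable":
        """The shipped 84-region Desikan-Killiany table.

        68 cortical, 14 subcortical and 2 cerebellar regions, split evenly
        between left and right hemispheres.
        """
        ref = resources.files("connectomlp.data").joinpath("dk84.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


# ---------------------------------------------------------------------------
# Connectome matrices
# ---------------------------------------------------------------------------

@dataclass
class ConnectomeMatrix:
    """One participant's symmetric non-negative edge-weight matrix."""

    weights: np.ndarray
    participant_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"weights must be square, got {w.shape}")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _read_numeric_matrix(path: str | Path) -> np.ndarray:
    text = Path(path).read_text()
    # builders emit either CSV or whitespace-delimited; commas normalise to spaces
    try:
        mat = np.loadtxt(_io.StringIO(text.replace(",", " ")), ndmin=2)
    except ValueError as exc:
        raise ConnectomeError(f"{path}: non-numeric content ({exc})") from exc
    return mat


def validate_connectome(
    weights: np.ndarray,
    n_nodes: int | None = None,
    *,
    context: str = "connectome",
) -> np.ndarray:
    """Validate and repair a raw weight matrix.

    Non-zero diagonals (self-connection counts emitted by some builders) are
    zeroed with a warning; asymmetry within ``ASYMMETRY_RTOL`` relative is
    repaired by averaging ``(w_ij + w_ji) / 2``; anything worse is an error.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ConnectomeError(f"{context}: matrix must be square, got {w.shape}")
    if n_nodes is not None and w.shape[0] != n_nodes:
        raise ConnectomeError(
            f"{context}: matrix is {w.shape[0]}x{w.shape[0]} but the node "
            f"table has {n_nodes} regions")
    if not np.all(np.isfinite(w)):
        raise ConnectomeError(f"{context}: non-finite entries")
    if np.any(w < 0):
        raise ConnectomeError(f"{context}: negative edge weights")
    scale = max(np.abs(w).max(), 1.0)
    asym = np.abs(w - w.T).max()
    if asym > ASYMMETRY_RTOL * scale:
        raise ConnectomeError(
            f"{context}: asymmetry {asym:.3g} exceeds tolerance "
            f"({ASYMMETRY_RTOL:g} relative)")
    if asym > 0:
        w = (w + w.T) / 2.0
    if np.any(np.diagonal(w) != 0):
        logger.warning("%s: zeroing %d non-zero diagonal entries",
                       context, int(np.count_nonzero(np.diagonal(w))))
        w = w.copy()
        np.fill_diagonal(w, 0.0)
    return w


def load_connectome(
    path: str | Path,
    node_table: NodeTable,
    participant_id: str = "",
    label: int | None = None,
) -> ConnectomeMatrix:
    """Load and validate one participant's connectome matrix file."""
    raw = _read_numeric_matrix(path)
    w = validate_connectome(raw, node_table.n_nodes, context=str(path))
    return ConnectomeMatrix(w, participant_id=participant_id, label=label)


def save_connectome(path: str | Path, matrix: ConnectomeMatrix | np.ndarray) -> None:
    """Write a connectome as a whitespace-delimited plain-text matrix."""
    w = matrix.weights if isinstance(matrix, ConnectomeMatrix) else np.asarray(matrix)
    np.savetxt(path, w, fmt="%.12g")


# ---------------------------------------------------------------------------
# Edge indexing and vectorization
# ---------------------------------------------------------------------------

def edge_index(i: int, j: int, n: int) -> int:
    """Flat index of edge ``(i, j)`` in the row-major strict upper triangle.

    The map is the bijection ``(i, j) with i < j  ->  0 .. n(n-1)/2 - 1``
    under which ``(0, 1) -> 0`` and ``(n-2, n-1) -> n(n-1)/2 - 1``.
    """
    if not (0 <= i < j < n):
        raise IndexError(f"need 0 <= i < j < n, got i={i}, j={j}, n={n}")
    return i * (2 * n - i - 1) // 2 + (j - i - 1)


def edge_pair(k: int, n: int) -> tuple[int, int]:
    """Inverse of :func:`edge_index`: the node pair at flat index ``k``."""
    n_edges = n * (n - 1) // 2
    if not (0 <= k < n_edges):
        raise IndexError(f"flat index {k} out of range for n={n}")
    # row starts are cumulative (n-1) + (n-2) + ...; solve by scan (n is small)
    i = 0
    row_start = 0
    while row_start + (n - i - 1) <= k:
        row_start += n - i - 1
        i += 1
    j = i + 1 + (k - row_start)
    return i, j


def vectorize(m: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    """Flatten the strict upper triangle into the canonical edge vector."""
    w = m.weights if isinstance(m, ConnectomeMatrix) else np.asarray(m)
    iu = np.triu_indices(w.shape[0], k=1)
    return w[iu].copy()


def devectorize(v: np.ndarray, n_nodes: int) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from an edge vector."""
    v = np.asarray(v, dtype=float)
    expected = n_nodes * (n_nodes - 1) // 2
    if v.shape != (expected,):
        raise ValueError(f"edge vector has length {v.size}, expected {expected}")
    w = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    w[iu] = v
    return w + w.T


def normalize(v: np.ndarray) -> np.ndarray:
    """Per-participant min-max scaling of an edge vector onto [0, 1].

    Removes the arbitrary inter-subject streamline-count scale; being
    per-participant, it cannot leak test-set statistics into training.
    """
    v = np.asarray(v, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ConnectomeError(
            "constant edge vector (max == min): degenerate connectome")
    return (v - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Participant manifest
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A labelled cohort of vectorised participants."""

    participant_ids: list[str]
    X: np.ndarray  # (n_participants, n_edges) edge vectors
    y: np.ndarray  # (n_participants,) int labels in {0, 1}

    def __len__(self) -> int:
        return len(self.participant_ids)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a participant manifest TSV (columns participant_id, path, label)."""
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    for col in ("participant_id", "path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest missing column {col!r}")
    if not set(df["label"].astype(int)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    return df


def load_cohort(
    manifest_path: str | Path,
    node_table: NodeTable,
    normalize_mode: str = "participant",
) -> Cohort:
    """Load, vectorize and normalize every participant in a manifest.

    ``normalize_mode``: ``"participant"`` (min-max per subject, default),
    ``"cohort"`` (single min-max over the pooled edge values) or ``"none"``.
    """
    if normalize_mode not in ("participant", "cohort", "none"):
        raise ValueError(f"unknown normalize_mode {normalize_mode!r}")
    df = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    ids, rows, labels = [], [], []
    for rec in df.itertuples(index=False):
        p = Path(rec.path)
        if not p.is_absolute():
            p = base / p
        m = load_connectome(p, node_table, participant_id=rec.participant_id,
                            label=int(rec.label))
        ids.append(rec.participant_id)
        rows.append(vectorize(m))
        labels.append(int(rec.label))
    X = np.vstack(rows)
    if normalize_mode == "participant":
        X = np.vstack([normalize(r) for r in X])
    elif normalize_mode == "cohort":
        lo, hi = X.min(), X.max()
        if hi == lo:
            raise ConnectomeError("constant cohort edge values")
        X = (X - lo) / (hi - lo)
    return Cohort(ids, X, np.asarray(labels, dtype=int))
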