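"""Gradient-score aggregation: edge scores, node scores, rankings.

After repeated cross-validation, every participant who was *correctly*
predicted as a held-out test case contributes one gradient sample per repeat:
the derivative of the network's output for the participant's true class with
respect to the 3486 input edges, taken under the fold model that made the
prediction.  Averaging those samples per class gives the per-edge *gradient
score*: positive means the edge pushes classification toward that group.
Summing the scores of all edges incident to a node gives the node's score
(its gradient "strength").

Two sample-set conventions are provided:

``per-class`` (default)
    each class's score averages the gradients of its own correctly
    predicted participants;
``shared``
    both classes' gradients are computed on the union of correctly
    predicted participants.  In probability mode this makes the two
    classes' score vectors exact negatives of each other — the
    positive-for-one-group / negative-for-the-other duality — mechanically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cv import RepeatedRun
from .io import NodeTable
from .mlp import GRADIENT_MODES, input_gradient

SAMPLE_SETS = ("per-class", "shared")


@dataclass
class GradientSamples:
    """Per-class stacks of raw gradient samples (one row per seed x participant)."""

    samples: dict[int, np.ndarray]
    mode: str
    sample_set: str

    def counts(self) -> dict[int, int]:
        return {c: s.shape[0] for c, s in self.samples.items()}


@dataclass
class SaliencyResult:
    """Aggregated per-class edge scores, node scores and bookkeeping."""

    edge_scores: dict[int, np.ndarray]   # class -> (n_edges,)
    node_scores: dict[int, np.ndarray]   # class -> (n_nodes,)
    contributing_count: dict[int, int]
    mode: str
    sample_set: str


@dataclass
class RankedList:
    """Top-k items in non-increasing score order (ties by ascending index)."""

    items: list
    scores: np.ndarray
    indices: np.ndarray


def collect_gradients(
    run: RepeatedRun,
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "probability",
    sample_set: str = "per-class",
) -> GradientSamples:
    """Input gradients of every correctly predicted held-out participant.

    For each repeat and each participant predicted correctly in that repeat,
    the gradient is taken under the model of the fold in which the
    participant was held out, for the participant's true class.  A
    participant misclassified in every repeat contributes no samples.
    """
    if mode not in GRADIENT_MODES:
        raise ValueError(f"unknown gradient mode {mode!r}")
    if sample_set not in SAMPLE_SETS:
        raise ValueError(f"unknown sample_set {sample_set!r}")
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    buckets: dict[int, list[np.ndarray]] = {0: [], 1: []}
    for res in run.results:
        if res.fold_models is None:
            raise ValueError(
                f"repeat with init_seed={res.init_seed} did not retain fold "
                "models (run with keep_models=True)")
        for p in np.flatnonzero(res.correct):
            model = res.fold_models[res.folds.fold_of[p]]
            if sample_set == "per-class":
                g = input_gradient(model, X[p], int(y[p]), mode=mode)
                buckets[int(y[p])].append(g)
            else:  # shared: both classes' gradients on the same input
                for c in (0, 1):
                    buckets[c].append(input_gradient(model, X[p], c, mode=mode))
    samples = {c: (np.vstack(v) if v else np.empty((0, X.shape[1])))
               for c, v in buckets.items()}
    return GradientSamples(samples=samples, mode=mode, sample_set=sample_set)


def aggregate_edge_scores(samples: GradientSamples) -> dict[int, np.ndarray]:
    """Arithmetic mean of each class's gradient samples, per edge."""
    out = {}
    for c, s in samples.samples.items():
        if s.shape[0] == 0:
            raise ValueError(f"class {c} has no correctly predicted "
                             "participants; no gradient samples to average")
        out[c] = s.mean(axis=0, dtype=np.float64)
    return out


def node_scores(edge_scores: np.ndarray, n_nodes: int) -> np.ndarray:
    """Node score = sum of gradient scores of the node's incident edges.

    Satisfies the handshake identity ``sum(node) = 2 * sum(edge)`` exactly
    (every edge has two endpoints).
    """
    g = np.asarray(edge_scores, dtype=np.float64)
    expected = n_nodes * (n_nodes - 1) // 2
    if g.shape != (expected,):
        raise ValueError(f"edge scores have length {g.size}, expected {expected}")
    iu, ju = np.triu_indices(n_nodes, k=1)
    s = np.zeros(n_nodes)
    np.add.at(s, iu, g)
    np.add.at(s, ju, g)
    return s


def compute_saliency(
    run: RepeatedRun,
    X: np.ndarray,
    y: np.ndarray,
    node_table: NodeTable,
    mode: str = "probability",
    sample_set: str = "per-class",
) -> SaliencyResult:
    """Full aggregation: collect, average, derive node scores."""
    samples = collect_gradients(run, X, y, mode=mode, sample_set=sample_set)
    edge = aggregate_edge_scores(samples)
    node = {c: node_scores(g, node_table.n_nodes) for c, g in edge.items()}
    return SaliencyResult(edge_scores=edge, node_scores=node,
                          contributing_count=samples.counts(),
                          mode=mode, sample_set=sample_set)


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------

def _rank_order(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=np.float64)
    # lexsort: primary key last -> descending score, ties by ascending index
    return np.lexsort((np.arange(scores.size), -scores))


def top_k_nodes(scores: np.ndarray, k: int, node_table: NodeTable) -> RankedList:
    """The k highest-scoring nodes by name."""
    scores = np.asarray(scores, dtype=np.float64)
    if k > scores.size:
        raise ValueError(f"k={k} exceeds {scores.size} nodes")
    order = _rank_order(scores)[:k]
    return RankedList(items=[node_table.names[i] for i in order],
                      scores=scores[order], indices=order)


def top_k_edges(scores: np.ndarray, k: int, node_table: NodeTable) -> RankedList:
    """The k highest-scoring edges as (name_i, name_j) pairs."""
    scores = np.asarray(scores, dtype=np.float64)
    if k > scores.size:
        raise ValueError(f"k={k} exceeds {scores.size} edges")
    iu, ju = np.triu_indices(node_table.n_nodes, k=1)
    order = _rank_order(scores)[:k]
    items = [(node_table.names[iu[e]], node_table.names[ju[e]]) for e in order]
    return RankedList(items=items, scores=scores[order], indices=order)


def cross_hemisphere_count(ranked_edges: RankedList, node_table: NodeTable) -> int:
    """How many listed edges join a left-hemisphere to a right-hemisphere node.

    Midline (``M``) endpoints never count as crossing.
    """
    iu, ju = np.triu_indices(node_table.n_nodes, k=1)
    count = 0
    for e in ranked_edges.indices:
        hi = node_table.hemispheres[iu[e]]
        hj = node_table.hemispheres[ju[e]]
        if {hi, hj} == {"L", "R"}:
            count += 1
    return count


def edge_rank_of(pairs: list[tuple[int, int]], scores: np.ndarray,
                 n_nodes: int) -> np.ndarray:
    """0-based rank (by descending score) of each given node pair."""
    from .io import edge_index
    order = _rank_order(scores)
    rank_of_flat = np.empty(order.size, dtype=int)
    rank_of_flat[order] = np.arange(order.size)
    return np.array([rank_of_flat[edge_index(i, j, n_nodes)] for i, j in pairs])
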