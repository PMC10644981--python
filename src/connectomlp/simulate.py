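"""Synthetic two-group connectome cohorts with planted, recoverable effects.

Real structural connectomes from the clinic cannot be shipped, so this module
generates cohorts that emulate their data model: symmetric, non-negative,
zero-diagonal 84x84 matrices of streamline-weight-like values.  The generative
model is deliberately minimal:

* a *backbone* mean network with hemispheric two-block topology — an edge
  between two regions exists with probability ``intra_hemisphere_density``
  when they share a hemisphere and ``inter_hemisphere_density`` otherwise,
  and present edges carry log-normal weights (streamline weights are positive
  and right-skewed);
* per-subject multiplicative log-normal noise on every present edge;
* a *planted* group effect: group-1 subjects have a chosen set of backbone
  edges multiplied by ``1 + effect_size``.  Planting cross-hemisphere edges
  emulates the interhemispheric connectivity differences expected of the
  focal-to-bilateral seizure phenotype.

Determinism: a single config seed drives everything through documented
derived streams — the backbone from ``default_rng((seed, 0))``, auto-chosen
planted edges from ``default_rng((seed, 1))`` and subject ``s`` (0-based,
across both groups) from ``default_rng(seed + 1 + s)`` — so individual
subjects are reproducible independent of cohort size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import (
    Cohort,
    ConnectomeMatrix,
    NodeTable,
    edge_index,
    normalize,
    save_connectome,
    validate_connectome,
    vectorize,
)


def make_node_table(n_nodes: int) -> NodeTable:
    """A node table for arbitrary ``n_nodes``: the shipped DK table at 84,
    otherwise a generic half-left / half-right split."""
    if n_nodes == 84:
        return NodeTable.default()
    half = (n_nodes + 1) // 2
    names = tuple(f"{'L' if i < half else 'R'}.Region{i:03d}"
                  for i in range(n_nodes))
    hemis = tuple("L" if i < half else "R" for i in range(n_nodes))
    return NodeTable(names, hemis)


@dataclass
class SimConfig:
    """Generator parameters.

    Defaults mirror the clinical study design this package targets: an
    84-region parcellation and a 20-control / 28-patient cohort (group 1,
    the larger group, carries the planted effect).  Densities and weight
    scales are chosen to resemble dense tractography connectomes; the weight
    scale itself is irrelevant downstream because edge vectors are min-max
    normalized per participant.
    """

    n_nodes: int = 84
    n_per_group: tuple[int, int] = (20, 28)
    intra_hemisphere_density: float = 0.6
    inter_hemisphere_density: float = 0.3
    base_weight_log_mean: float = 0.0
    base_weight_log_sd: float = 1.0
    subject_noise_sd: float = 0.3
    planted_edges: list[tuple[int, int]] | None = None
    n_planted: int = 20
    n_cross_hemisphere_planted: int = 2
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not (0 < self.intra_hemisphere_density <= 1):
            raise ValueError("intra_hemisphere_density must be in (0, 1]")
        # inter density 0 is a legitimate boundary: a fully lateralised network
        if not (0 <= self.inter_hemisphere_density <= 1):
            raise ValueError("inter_hemisphere_density must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be >= 0")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("each group needs at least one subject")
        if self.planted_edges is not None:
            self.planted_edges = [(int(i), int(j)) for i, j in self.planted_edges]
            for i, j in self.planted_edges:
                if not (0 <= i < j < self.n_nodes):
                    raise ValueError(f"planted edge ({i}, {j}) is not an "
                                     f"upper-triangle pair for n={self.n_nodes}")


@dataclass
class SimCohort:
    """A generated cohort plus its ground truth."""

    connectomes: list[ConnectomeMatrix]
    node_table: NodeTable
    backbone: np.ndarray
    #: planted edges as (i, j, multiplier) triples — the recoverable truth
    ground_truth: list[tuple[int, int, float]]
    config: SimConfig

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.label for m in self.connectomes], dtype=int)

    @property
    def planted_pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j, _ in self.ground_truth]


def _same_hemisphere(table: NodeTable) -> np.ndarray:
    """Boolean matrix: True where two nodes share an L or R hemisphere."""
    h = np.array(table.hemispheres)
    same = (h[:, None] == h[None, :]) & (h[:, None] != "M")
    return same


def generate_backbone(config: SimConfig,
                      node_table: NodeTable | None = None) -> np.ndarray:
    """The cohort-mean network: two-block topology with log-normal weights."""
    table = node_table or make_node_table(config.n_nodes)
    if table.n_nodes != config.n_nodes:
        raise ValueError("node table size does not match config.n_nodes")
    n = config.n_nodes
    rng = np.random.default_rng((config.seed, 0))
    iu = np.triu_indices(n, k=1)
    same = _same_hemisphere(table)[iu]
    dens = np.where(same, config.intra_hemisphere_density,
                    config.inter_hemisphere_density)
    present = rng.random(iu[0].size) < dens
    weights = np.where(
        present,
        rng.lognormal(config.base_weight_log_mean, config.base_weight_log_sd,
                      iu[0].size),
        0.0)
    w = np.zeros((n, n))
    w[iu] = weights
    return w + w.T


def _auto_planted(config: SimConfig, backbone: np.ndarray,
                  table: NodeTable, rng: np.random.Generator
                  ) -> list[tuple[int, int]]:
    """Pick planted edges from the backbone: the requested number of
    cross-hemisphere edges, the rest intra-hemisphere."""
    n = config.n_nodes
    iu = np.triu_indices(n, k=1)
    present = backbone[iu] > 0
    cross = ~_same_hemisphere(table)[iu]
    n_cross = config.n_cross_hemisphere_planted
    n_intra = config.n_planted - n_cross
    if n_cross < 0 or n_intra < 0:
        raise ValueError("n_cross_hemisphere_planted must be in [0, n_planted]")
    picks = []
    for mask, count, kind in ((present & cross, n_cross, "cross-hemisphere"),
                              (present & ~cross, n_intra, "intra-hemisphere")):
        pool = np.flatnonzero(mask)
        if pool.size < count:
            raise ValueError(f"backbone has only {pool.size} {kind} edges, "
                             f"{count} requested")
        picks.extend(rng.choice(pool, size=count, replace=False))
    return sorted((int(iu[0][k]), int(iu[1][k])) for k in picks)


def generate_cohort(config: SimConfig,
                    node_table: NodeTable | None = None) -> SimCohort:
    """Generate the full two-group cohort with ground truth.

    Each subject's matrix is ``backbone * exp(eps)`` with i.i.d.
    ``Normal(0, subject_noise_sd^2)`` noise per present edge; group-1
    subjects additionally carry ``(1 + effect_size)`` on the planted edges.
    """
    table = node_table or make_node_table(config.n_nodes)
    backbone = generate_backbone(config, table)
    rng = np.random.default_rng((config.seed, 1))  # planted-edge selection stream
    if config.planted_edges is not None:
        planted = list(config.planted_edges)
    else:
        planted = _auto_planted(config, backbone, table, rng)
    for i, j in planted:
        if backbone[i, j] == 0:
            raise ValueError(f"planted edge ({i}, {j}) is absent from the backbone")

    n = config.n_nodes
    iu = np.triu_indices(n, k=1)
    base = backbone[iu]
    present = base > 0
    multiplier = 1.0 + config.effect_size
    boost = np.ones_like(base)
    for i, j in planted:
        boost[edge_index(i, j, n)] = multiplier

    connectomes: list[ConnectomeMatrix] = []
    s = 0
    for label, n_group in enumerate(config.n_per_group):
        for _ in range(n_group):
            srng = np.random.default_rng(config.seed + 1 + s)
            eps = srng.standard_normal(base.size) * config.subject_noise_sd
            vals = base * np.exp(eps) * (boost if label == 1 else 1.0)
            vals[~present] = 0.0
            w = np.zeros((n, n))
            w[iu] = vals
            w = w + w.T
            connectomes.append(ConnectomeMatrix(
                w, participant_id=f"sub-{s:03d}", label=label))
            s += 1
    truth = [(i, j, multiplier) for i, j in planted]
    return SimCohort(connectomes, table, backbone, truth, config)


def cohort_arrays(sim: SimCohort, normalize_mode: str = "participant") -> Cohort:
    """Vectorize (and optionally normalize) a simulated cohort for training."""
    rows = []
    for m in sim.connectomes:
        v = vectorize(m)
        rows.append(normalize(v) if normalize_mode == "participant" else v)
    X = np.vstack(rows)
    if normalize_mode == "cohort":
        lo, hi = X.min(), X.max()
        X = (X - lo) / (hi - lo)
    elif normalize_mode not in ("participant", "none"):
        raise ValueError(f"unknown normalize_mode {normalize_mode!r}")
    return Cohort([m.participant_id for m in sim.connectomes], X, sim.labels)


# ---------------------------------------------------------------------------
# On-disk cohort layout
# ---------------------------------------------------------------------------

def write_cohort(sim: SimCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write one matrix file per subject, a manifest TSV and ground truth JSON.

    Returns the paths of everything written, keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat_dir = out / "connectomes"
    mat_dir.mkdir(exist_ok=True)
    rows = []
    for m in sim.connectomes:
        path = mat_dir / f"{m.participant_id}.txt"
        save_connectome(path, m)
        rows.append((m.participant_id, path.relative_to(out), m.label))
    manifest = out / "manifest.tsv"
    with manifest.open("w") as f:
        f.write("participant_id\tpath\tlabel\n")
        for pid, rel, label in rows:
            f.write(f"{pid}\t{rel}\t{label}\n")
    truth_path = out / "ground_truth.json"
    cfg = asdict(sim.config)
    cfg["n_per_group"] = list(cfg["n_per_group"])
    truth_path.write_text(json.dumps({
        "planted_edges": [[i, j, mult] for i, j, mult in sim.ground_truth],
        "config": cfg,
    }, indent=2))
    return {"manifest": manifest, "ground_truth": truth_path,
            "connectome_dir": mat_dir}
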