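"""Repeated-seed stratified 5-fold cross-validation and best-model selection.

The experimental protocol: split the cohort once into k stratified folds,
then repeat training across many network-initialization seeds — the folds
stay fixed while only the initial weights vary.  Each repeat trains one
model per fold and predicts the held-out fold, so every participant is a
test case exactly once per repeat; *pooled accuracy* is the fraction of all
N held-out predictions that are correct (an exact rational m/N).  The *best
model* is the seed with maximal pooled accuracy, ties broken by lowest seed.

Per-fold trained parameters are retained because saliency analysis needs the
model under which each participant was (correctly) predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .mlp import MLPParams, TrainConfig, init_params, predict_batch, train


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified partition of participants into k folds."""

    fold_of: np.ndarray  # (N,) fold index per participant
    k: int
    split_seed: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fold_of)
        if f.min() < 0 or f.max() >= self.k:
            raise ValueError("fold indices out of range")
        if len(np.unique(f)) != self.k:
            raise ValueError("some fold is empty")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def make_folds(labels: np.ndarray, k: int = 5, split_seed: int = 0) -> FoldAssignment:
    """Stratified fold assignment, deterministic given ``split_seed``.

    Stratification keeps per-fold class proportions within one member of the
    cohort proportion and guarantees both classes appear in every fold — at
    clinical cohort sizes an unstratified split can produce a single-class
    test fold, for which accuracy per class is undefined.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot stratify "
            f"into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=split_seed)
    fold_of = np.empty(y.size, dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        fold_of[test_idx] = f
    return FoldAssignment(fold_of, k, split_seed)


@dataclass
class CVResult:
    """One repeat: per-participant held-out predictions under one init seed."""

    init_seed: int
    predictions: np.ndarray  # (N,) predicted class for each held-out participant
    correct: np.ndarray      # (N,) bool
    pooled_accuracy: float
    folds: FoldAssignment
    fold_models: list[MLPParams] | None
    loss_curves: list[np.ndarray] | None = None


@dataclass
class RepeatedRun:
    """All repeats plus the best-model summary."""

    results: list[CVResult]
    best_seed: int
    best_accuracy: float

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.pooled_accuracy for r in self.results])

    @property
    def best(self) -> CVResult:
        return next(r for r in self.results if r.init_seed == self.best_seed)


def _derived_init_seed(init_seed: int, fold: int, k: int) -> int:
    # distinct stream per (repeat, fold); documented so runs are replayable
    return init_seed * k + fold


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldAssignment,
    init_seed: int,
    cfg: TrainConfig | None = None,
    keep_models: bool = True,
) -> CVResult:
    """One 5-fold cross-validation pass under a single initialization seed.

    For each fold the network is initialized from the derived seed
    ``init_seed * k + fold``, trained on the other folds, and used to predict
    the held-out fold.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    n = y.size
    predictions = np.full(n, -1, dtype=int)
    fold_models: list[MLPParams] = []
    loss_curves: list[np.ndarray] = []
    for f in range(folds.k):
        tr = folds.train_indices(f)
        te = folds.test_indices(f)
        params = init_params(X.shape[1], _derived_init_seed(init_seed, f, folds.k),
                             hidden=cfg.hidden, dtype=cfg.dtype)
        try:
            params, losses = train(params, X[tr], y[tr], cfg)
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {f} "
                               f"(init_seed={init_seed})") from exc
        predictions[te] = predict_batch(params, X[te])
        fold_models.append(params)
        loss_curves.append(losses)
    correct = predictions == y
    return CVResult(
        init_seed=init_seed,
        predictions=predictions,
        correct=correct,
        pooled_accuracy=float(np.count_nonzero(correct)) / n,
        folds=folds,
        fold_models=fold_models if keep_models else None,
        loss_curves=loss_curves,
    )


def run_repeated(
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldAssignment,
    n_seeds: int,
    cfg: TrainConfig | None = None,
    base_init_seed: int = 0,
    refold_per_seed: bool = False,
    keep_models: bool = True,
    progress: bool = False,
) -> RepeatedRun:
    """Repeat ``run_cv`` over init seeds ``base..base+n_seeds-1``.

    The fold assignment is held fixed across repeats by default (only the
    initial network weights are re-randomized); ``refold_per_seed`` instead
    re-draws the stratified split for every repeat, using
    ``folds.split_seed + init_seed``.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    cfg = cfg or TrainConfig()
    results = []
    for s in range(base_init_seed, base_init_seed + n_seeds):
        f = (make_folds(y, folds.k, folds.split_seed + s)
             if refold_per_seed else folds)
        res = run_cv(X, y, f, s, cfg, keep_models=keep_models)
        results.append(res)
        if progress:
            print(f"  seed {s}: pooled accuracy {res.pooled_accuracy:.4f}")
    accs = np.array([r.pooled_accuracy for r in results])
    best_idx = int(np.argmax(accs))  # argmax returns the first = lowest seed on ties
    return RepeatedRun(
        results=results,
        best_seed=results[best_idx].init_seed,
        best_accuracy=float(accs[best_idx]),
    )
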