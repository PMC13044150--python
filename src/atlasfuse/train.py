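"""Nested cross-validation training harness.

Protocol: stratified outer folds estimate generalization (10 folds for
large cohorts, 5 for small); on each outer-training set an inner stratified
cross-validation grid search selects hyperparameters by mean inner AUC; the
winning configuration is retrained on the whole outer-training set and
scored once on the held-out outer-test fold.  Outer-test subjects never
participate in selection or training — an explicit leakage guard asserts
the disjointness on every run.

Optimization: AdamW, cosine-annealed learning rate from 0.001 to 0,
label-smoothed cross-entropy, batch size 8, dropout 0.3 inside the model.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import autodiff as ad
from .autodiff import Tensor
from .fusion import MultiAtlasClassifier, predict_label
from .nn import AdamW

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12  #: probabilities are clamped here before the log


@dataclass
class TrainConfig:
    """Optimization and protocol settings (defaults follow the reference
    protocol: lr 0.001 with cosine annealing, batch 8, 200 epochs)."""

    learning_rate: float = 1e-3
    min_lr: float = 0.0
    batch_size: int = 8
    epochs: int = 200
    label_smoothing_eps: float = 0.1
    fusion_warmup_frac: float = 0.0  #: fraction of epochs with uniform fusion
    outer_folds: int = 10
    inner_folds: int = 3
    seed: int = 0
    weight_decay: float = 1e-2
    grid: dict[str, list] = field(default_factory=lambda: {"label_smoothing_eps": [0.1]})
    selection_metric: str = "auc"

    def __post_init__(self):
        if not 0.0 <= self.label_smoothing_eps < 0.5:
            raise ValueError("label_smoothing_eps must be in [0, 0.5)")
        if not 0.0 <= self.fusion_warmup_frac <= 1.0:
            raise ValueError("fusion_warmup_frac must be in [0, 1]")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")


def smoothed_cross_entropy(probabilities: Tensor, label: int, eps: float) -> Tensor:
    """Cross-entropy against the label-smoothed target (1-eps, eps).

    ``eps = 0`` recovers the standard cross-entropy.  Probabilities below
    ``PROB_FLOOR`` are clamped (and the clamp logged) so a confidently
    wrong model yields a large finite loss rather than an infinity.
    """
    if not 0.0 <= eps < 0.5:
        raise ValueError("eps must be in [0, 0.5)")
    target = np.full(2, eps)
    target[label] = 1.0 - eps
    clamped = probabilities.data < PROB_FLOOR
    if clamped.any() and target[clamped].any():
        logger.warning("probability clamped to %g in cross-entropy", PROB_FLOOR)
    mask = (~clamped).astype(float)
    safe = probabilities * Tensor(mask) + Tensor(clamped * PROB_FLOOR)
    return -(Tensor(target) * ad.log(safe)).sum()


def cosine_lr(step: int, total_steps: int, base_lr: float = 1e-3, min_lr: float = 0.0) -> float:
    """Half-cosine interpolation from ``base_lr`` (step 0) to ``min_lr``."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if not 0 <= step <= total_steps:
        raise ValueError("step must lie in [0, total_steps]")
    return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + math.cos(math.pi * step / total_steps))


def evaluate_metrics(
    scores: np.ndarray, predictions: np.ndarray, labels: np.ndarray
) -> dict[str, float | None]:
    """ACC, SEN (case recall), SPE (control recall), AUC for one fold.

    AUC is the rank-based probability that a random case outscores a random
    control, with half-credit for ties (equivalent to exhaustive pair
    counting).  A one-class fold gets ``auc=None`` with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if not (len(scores) == len(predictions) == len(labels)):
        raise ValueError("scores, predictions and labels must align")
    pos, neg = labels == 1, labels == 0
    tp = int(((predictions == 1) & pos).sum())
    tn = int(((predictions == 0) & neg).sum())
    fp = int(((predictions == 1) & neg).sum())
    fn = int(((predictions == 0) & pos).sum())
    n_pos, n_neg = pos.sum(), neg.sum()
    out: dict[str, float | None] = {
        "acc": (tp + tn) / len(labels),
        "sen": tp / n_pos if n_pos else None,
        "spe": tn / n_neg if n_neg else None,
    }
    if n_pos == 0 or n_neg == 0:
        logger.warning("one-class fold: AUC undefined, excluded from aggregation")
        out["auc"] = None
        return out
    ranks = rankdata(scores, method="average")
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    out["auc"] = float(u / (n_pos * n_neg))
    return out


@dataclass
class FoldResult:
    fold: int
    test_indices: np.ndarray
    chosen: dict
    metrics: dict[str, float | None]
    scores: np.ndarray
    predictions: np.ndarray


@dataclass
class EvalMetrics:
    """Per-fold metrics plus mean/sd aggregates over outer folds."""

    folds: list[FoldResult]

    def aggregate(self) -> dict[str, tuple[float, float]]:
        out = {}
        for m in ("acc", "sen", "spe", "auc"):
            vals = [f.metrics[m] for f in self.folds if f.metrics[m] is not None]
            arr = np.asarray(vals, dtype=float)
            out[m] = (float(arr.mean()), float(arr.std(ddof=0))) if len(arr) else (math.nan, math.nan)
        return out

    def summary(self) -> dict:
        agg = self.aggregate()
        return {
            "n_folds": len(self.folds),
            **{f"{m}_mean": agg[m][0] for m in agg},
            **{f"{m}_sd": agg[m][1] for m in agg},
            "chosen_per_fold": [f.chosen for f in self.folds],
        }


Cohort = list[dict]  # one dict of atlas -> BrainGraph per subject


def train_model(
    model: MultiAtlasClassifier,
    cohort: Cohort,
    labels: np.ndarray,
    config: TrainConfig,
    seed: int,
) -> list[float]:
    """AdamW training loop; returns the per-epoch mean loss log.

    Fully deterministic given ``seed`` (shuffling and dropout share one
    generator).  Raises ``FloatingPointError`` naming the epoch if the loss
    diverges.
    """
    if not cohort:
        raise ValueError("empty training split")
    rng = np.random.default_rng(seed)
    opt = AdamW(model.params, lr=config.learning_rate, weight_decay=config.weight_decay)
    n = len(cohort)
    batches_per_epoch = math.ceil(n / config.batch_size)
    total_steps = config.epochs * batches_per_epoch
    step = 0
    warmup_epochs = int(round(config.fusion_warmup_frac * config.epochs))
    log: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        uniform = epoch < warmup_epochs
        for b in range(batches_per_epoch):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            opt.zero_grad()
            batch_loss = None
            for i in idx:
                probs, _, _ = model.forward(cohort[i], rng=rng, uniform_fusion=uniform)
                loss = smoothed_cross_entropy(
                    probs, int(labels[i]), config.label_smoothing_eps
                )
                batch_loss = loss if batch_loss is None else batch_loss + loss
            batch_loss = batch_loss / len(idx)
            if not np.isfinite(batch_loss.data):
                raise FloatingPointError(f"loss diverged at epoch {epoch}")
            batch_loss.backward()
            opt.lr = cosine_lr(step, total_steps, config.learning_rate, config.min_lr)
            opt.step()
            step += 1
            epoch_losses.append(float(batch_loss.data))
        log.append(float(np.mean(epoch_losses)))
    model.trained = True
    return log


def _evaluate_split(model: MultiAtlasClassifier, cohort: Cohort, labels: np.ndarray):
    scores = np.array([model.predict_proba(g)[1] for g in cohort])
    preds = np.array([predict_label(np.array([1 - s, s])) for s in scores])
    return scores, preds, evaluate_metrics(scores, preds, labels)


def _grid_combinations(grid: dict[str, list]) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _apply_overrides(config: TrainConfig, overrides: dict) -> TrainConfig:
    train_keys = {k: v for k, v in overrides.items() if hasattr(config, k)}
    return replace(config, **train_keys)


def assert_no_leakage(train_idx: np.ndarray, test_idx: np.ndarray) -> None:
    overlap = set(map(int, train_idx)) & set(map(int, test_idx))
    if overlap:
        raise AssertionError(f"leakage: subjects {sorted(overlap)} in train and test")


def nested_cv(
    cohort: Cohort,
    labels: np.ndarray,
    model_builder,
    config: TrainConfig,
) -> EvalMetrics:
    """Nested stratified cross-validation with inner-loop grid search.

    ``model_builder(overrides, seed)`` must return a fresh
    :class:`MultiAtlasClassifier` for the given hyperparameter overrides.
    Grid entries that match :class:`TrainConfig` fields override training
    settings; all entries are also passed to the builder.  With a
    single-configuration grid the inner loop is skipped (selection is
    trivial).  Model selection uses mean inner-fold AUC by default.
    """
    labels = np.asarray(labels)
    combos = _grid_combinations(config.grid)
    outer = StratifiedKFold(
        n_splits=config.outer_folds, shuffle=True, random_state=config.seed
    )
    fold_results: list[FoldResult] = []
    all_test: list[np.ndarray] = []
    for fold, (train_idx, test_idx) in enumerate(outer.split(np.zeros(len(labels)), labels)):
        assert_no_leakage(train_idx, test_idx)
        if len(combos) == 1:
            best = combos[0]
        else:
            inner = StratifiedKFold(
                n_splits=config.inner_folds,
                shuffle=True,
                random_state=config.seed + 1000 + fold,
            )
            best, best_score = None, -np.inf
            for combo in combos:
                inner_scores = []
                cfg_c = _apply_overrides(config, combo)
                for j, (fit_rel, val_rel) in enumerate(
                    inner.split(np.zeros(len(train_idx)), labels[train_idx])
                ):
                    fit_idx, val_idx = train_idx[fit_rel], train_idx[val_rel]
                    assert_no_leakage(fit_idx, test_idx)
                    assert_no_leakage(val_idx, test_idx)
                    model = model_builder(combo, seed=config.seed + 31 * fold + j)
                    train_model(
                        model, [cohort[i] for i in fit_idx], labels[fit_idx], cfg_c,
                        seed=config.seed + 97 * fold + j,
                    )
                    _, _, metrics = _evaluate_split(
                        model, [cohort[i] for i in val_idx], labels[val_idx]
                    )
                    value = metrics[config.selection_metric]
                    if value is not None:
                        inner_scores.append(value)
                mean_score = float(np.mean(inner_scores)) if inner_scores else -np.inf
                if mean_score > best_score:
                    best, best_score = combo, mean_score
        cfg_best = _apply_overrides(config, best)
        model = model_builder(best, seed=config.seed + 7919 * (fold + 1))
        train_model(
            model, [cohort[i] for i in train_idx], labels[train_idx], cfg_best,
            seed=config.seed + 104729 * (fold + 1),
        )
        scores, preds, metrics = _evaluate_split(
            model, [cohort[i] for i in test_idx], labels[test_idx]
        )
        fold_results.append(
            FoldResult(fold, test_idx.copy(), dict(best), metrics, scores, preds)
        )
        all_test.append(test_idx)
        logger.info("outer fold %d: %s (chosen %s)", fold, metrics, best)
    covered = np.concatenate(all_test)
    if len(set(map(int, covered))) != len(labels):
        raise AssertionError("outer folds do not partition the cohort")
    return EvalMetrics(fold_results)


def nested_cv_with_models(
    cohort: Cohort,
    labels: np.ndarray,
    model_builder,
    config: TrainConfig,
) -> tuple[EvalMetrics, list[tuple[MultiAtlasClassifier, np.ndarray, np.ndarray]]]:
    """Like :func:`nested_cv` but also returns, per outer fold, the trained
    model and its (train_indices, test_indices) — needed by the
    interpretability pipeline, which averages attention over training
    subjects of each fold."""
    labels = np.asarray(labels)
    combos = _grid_combinations(config.grid)
    if len(combos) != 1:
        raise ValueError("nested_cv_with_models supports single-configuration grids")
    outer = StratifiedKFold(
        n_splits=config.outer_folds, shuffle=True, random_state=config.seed
    )
    fold_results, models = [], []
    for fold, (train_idx, test_idx) in enumerate(outer.split(np.zeros(len(labels)), labels)):
        assert_no_leakage(train_idx, test_idx)
        cfg = _apply_overrides(config, combos[0])
        model = model_builder(combos[0], seed=config.seed + 7919 * (fold + 1))
        train_model(
            model, [cohort[i] for i in train_idx], labels[train_idx], cfg,
            seed=config.seed + 104729 * (fold + 1),
        )
        scores, preds, metrics = _evaluate_split(
            model, [cohort[i] for i in test_idx], labels[test_idx]
        )
        fold_results.append(
            FoldResult(fold, test_idx.copy(), dict(combos[0]), metrics, scores, preds)
        )
        models.append((model, train_idx.copy(), test_idx.copy()))
    return EvalMetrics(fold_results), models
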