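"""Data splitting, the training loop, metrics, and the multi-trial protocol.

The benchmark protocol: 165 amyloid and 382 non-amyloid proteins are
stratified into train/validation/test partitions of 393/44/110 sequences
(117/15/33 positives and 276/29/77 negatives).  Models train with Adam
(learning rate 0.001) on binary cross-entropy for up to 40 epochs; the
weights from the epoch with minimum validation loss are kept.  Evaluation
reports AUROC (rank-based, midrank tie handling) plus balanced accuracy,
MCC and F1 at the 0.5 threshold.  Robustness is assessed over repeated
seeded trials, reporting per-metric mean and standard deviation.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io_tokenize import ProteinRecord, TokenizedBatch, tokenize
from .network import Adam, ModelConfig, SequenceClassifier, build_model

#: Per-class partition counts from the published benchmark.
PAPER_POS_COUNTS = (117, 15, 33)
PAPER_NEG_COUNTS = (276, 29, 77)


class CountError(ValueError):
    """Not enough records of a class to satisfy the split."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. one-class test set)."""


@dataclass
class SplitSpec:
    """Exact per-class counts for (train, validation, test) partitions."""

    pos_counts: tuple = PAPER_POS_COUNTS
    neg_counts: tuple = PAPER_NEG_COUNTS
    seed: int = 0

    @classmethod
    def proportional(cls, n_pos: int, n_neg: int, seed: int = 0) -> "SplitSpec":
        """Scale the benchmark's partition fractions to other class sizes."""
        def scale(n, ref):
            total_ref = sum(ref)
            counts = [int(round(n * c / total_ref)) for c in ref[1:]]
            counts = [max(c, 1) for c in counts]
            return (n - sum(counts), *counts)

        pos = scale(n_pos, PAPER_POS_COUNTS)
        neg = scale(n_neg, PAPER_NEG_COUNTS)
        if min(pos) < 1 or min(neg) < 1:
            raise CountError(
                f"cannot build a 3-way split from {n_pos} positives / "
                f"{n_neg} negatives"
            )
        return cls(pos_counts=pos, neg_counts=neg, seed=seed)


def stratified_split(
    records: Sequence[ProteinRecord], spec: SplitSpec
) -> tuple[list, list, list]:
    """Seeded stratified partition with exactly the spec's per-class counts.

    Positives and negatives are shuffled independently with the spec's seed
    and dealt into train/validation/test.  The same seed always yields the
    same member sets.
    """
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    for cls_name, items, counts in (
        ("positive", pos, spec.pos_counts), ("negative", neg, spec.neg_counts)
    ):
        need = sum(counts)
        if len(items) < need:
            raise CountError(
                f"need {need} {cls_name} records, got {len(items)} "
                f"(deficit {need - len(items)})"
            )
    rng = np.random.default_rng(spec.seed)
    parts: list[list[ProteinRecord]] = [[], [], []]
    for items, counts in ((pos, spec.pos_counts), (neg, spec.neg_counts)):
        order = rng.permutation(len(items))
        start = 0
        for k, count in enumerate(counts):
            parts[k].extend(items[i] for i in order[start:start + count])
            start += count
    return parts[0], parts[1], parts[2]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """AUROC, balanced accuracy, MCC and F1 for one model on one set."""

    auroc: float
    balanced_accuracy: float
    mcc: float
    f1: float
    threshold: float = 0.5
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def as_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
            "f1": self.f1,
            "threshold": self.threshold,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
        }


def confusion_counts(y_true, y_pred) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    return tp, fp, fn, tn


def mcc_from_counts(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation; 0 by convention when a denominator factor is 0."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def compute_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Score continuous predictions against binary labels.

    AUROC uses the rank-based (Mann-Whitney) estimator with midrank tie
    handling; the thresholded metrics come from the confusion matrix.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise UndefinedMetricError(
            "AUROC needs at least one member of each class"
        )
    auroc = float(roc_auc_score(y_true, scores))
    y_pred = (scores >= threshold).astype(int)
    tp, fp, fn, tn = confusion_counts(y_true, y_pred)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ba = 0.5 * (sens + spec)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return EvalReport(
        auroc=auroc, balanced_accuracy=ba, mcc=mcc_from_counts(tp, fp, fn, tn),
        f1=f1, threshold=threshold, tp=tp, fp=fp, fn=fn, tn=tn,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization protocol: Adam on binary cross-entropy.

    Defaults follow the published protocol (learning rate 0.001, up to 40
    epochs, minimum-validation-loss epoch selection).  Batch size 32 is the
    package's choice for a ~400-sequence training set.
    """

    learning_rate: float = 1e-3
    max_epochs: int = 40
    batch_size: int = 32
    seed: int = 0
    max_len: Optional[int] = 1000

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch normalization)")


def _length_sorted_batches(records, batch_size):
    """Group records into batches of similar length to limit padding."""
    order = sorted(range(len(records)), key=lambda i: len(records[i].sequence))
    return [
        [records[i] for i in order[s:s + batch_size]]
        for s in range(0, len(order), batch_size)
    ]


def predict_records(
    model: SequenceClassifier, records, max_len=None, batch_size: int = 64
) -> np.ndarray:
    """Evaluation-mode probabilities for a list of records (chunked)."""
    out = []
    for chunk in _length_sorted_batches(records, batch_size):
        batch = tokenize(chunk, max_len=max_len)
        out.append((chunk, model.predict_proba(batch)))
    # restore input order
    probs = np.empty(len(records), dtype=float)
    pos_of = {id(r): i for i, r in enumerate(records)}
    for chunk, p in out:
        for r, v in zip(chunk, p):
            probs[pos_of[id(r)]] = v
    return probs


def train(
    model: SequenceClassifier,
    train_records: Sequence[ProteinRecord],
    val_records: Sequence[ProteinRecord],
    config: TrainConfig,
) -> tuple[SequenceClassifier, dict, int]:
    """Train with Adam/BCE, returning minimum-validation-loss weights.

    Returns ``(model, history, best_epoch)`` where ``history`` maps
    ``train_loss``/``val_loss`` to per-epoch lists and ``best_epoch`` is the
    0-based epoch whose weights were restored.
    """
    if not train_records or not val_records:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.params, lr=config.learning_rate)
    batches = [
        tokenize(chunk, max_len=config.max_len)
        for chunk in _length_sorted_batches(train_records, config.batch_size)
    ]
    val_y = np.array([r.label for r in val_records], dtype=float)
    history = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(batches))
        total, n_seen = 0.0, 0
        for bi in order:
            batch = batches[bi]
            y = batch.labels.astype(float)
            loss, grads = model.loss_and_grads(batch, y)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}"
                )
            optimizer.step(model.params, grads)
            model.params["embedding"][0] = 0.0
            total += loss * len(batch)
            n_seen += len(batch)
        train_loss = total / n_seen
        val_scores = predict_records(
            model, val_records, max_len=config.max_len)
        val_loss = _bce(val_scores, val_y)
        if not np.isfinite(val_loss):
            raise DivergenceError(
                f"non-finite validation loss at epoch {epoch}"
            )
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
    model.load_state_dict(best_state)
    return model, history, best_epoch


def _bce(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def evaluate(
    model: SequenceClassifier,
    records: Sequence[ProteinRecord],
    threshold: float = 0.5,
    max_len: Optional[int] = 1000,
) -> EvalReport:
    """Score a trained model on labeled records."""
    y = np.array([r.label for r in records])
    scores = predict_records(model, records, max_len=max_len)
    return compute_metrics(y, scores, threshold=threshold)


# ---------------------------------------------------------------------------
# Multi-trial robustness protocol
# ---------------------------------------------------------------------------

def run_trials(
    records: Sequence[ProteinRecord],
    model_config: ModelConfig,
    train_config: TrainConfig,
    n_trials: int = 10,
    split_spec: Optional[SplitSpec] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat split/init/train/evaluate over seeded trials.

    Trial ``t`` derives every random stream from ``base_seed + t`` (split,
    weight initialization, batch shuffling).  Returns the per-trial metric
    table and a mean/SD summary.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if split_spec is None:
        pos = sum(1 for r in records if r.label == 1)
        neg = sum(1 for r in records if r.label == 0)
        if (pos, neg) == (sum(PAPER_POS_COUNTS), sum(PAPER_NEG_COUNTS)):
            split_spec = SplitSpec()
        else:
            split_spec = SplitSpec.proportional(pos, neg)
    rows = []
    for t in range(n_trials):
        seed = train_config.seed + t
        try:
            spec_t = SplitSpec(
                split_spec.pos_counts, split_spec.neg_counts, seed)
            train_set, val_set, test_set = stratified_split(records, spec_t)
            mc = copy.deepcopy(model_config)
            mc.seed = seed
            tc = copy.deepcopy(train_config)
            tc.seed = seed
            model = build_model(mc)
            model, _, _ = train(model, train_set, val_set, tc)
            report = evaluate(model, test_set, max_len=tc.max_len)
        except (DivergenceError, CountError) as exc:
            raise type(exc)(f"trial {t}: {exc}") from exc
        rows.append({"trial": t + 1, **{
            k: report.as_dict()[k]
            for k in ("auroc", "balanced_accuracy", "mcc", "f1")
        }})
    table = pd.DataFrame(rows)
    metrics = ["auroc", "balanced_accuracy", "mcc", "f1"]
    summary = pd.DataFrame({
        "mean": table[metrics].mean(),
        "sd": table[metrics].std(ddof=1) if n_trials > 1
        else pd.Series(0.0, index=metrics),
    })
    return table, summary
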