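"""Metrics, Hamming diversity, isolated-label post-processing, and the
subject-independent validation protocols (two-fold CV fitness and
leave-one-subject-out assessment).

The positive class throughout is the A phase.  Accuracy, sensitivity and
specificity use their standard definitions (Sen = TP/(TP+FN),
Spe = TN/(TN+FP)); AUC is the area under the ROC curve; the "mean metric"
(arithmetic mean of Acc/Sen/Spe) summarizes how balanced a result is under
heavy class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.metrics import roc_auc_score

from .fusion_model import (
    FusionModel,
    TrainingHyperparams,
    build_model,
    predict_scores,
    select_threshold,
    train,
)
from .encoding import ModelConfig
from .preprocessing import make_windows, preprocess_recording, windows_to_arrays
from .synthetic_data import Recording

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "confusion_from_predictions",
    "metrics",
    "roc_auc",
    "mean_metric",
    "postprocess",
    "diversity",
    "split_two_folds",
    "tfcv_fitness",
    "loo_evaluate",
    "summarize_loo",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with "A" as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalResult:
    """One evaluation cycle's outcome (typically one held-out subject)."""

    subject_id: str
    confusion: ConfusionCounts
    acc: float
    sen: float
    spe: float
    auc: float
    threshold: float

    @property
    def mean_metric(self) -> float:
        return mean_metric(self.acc, self.sen, self.spe)


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics(confusion: ConfusionCounts) -> tuple[float, float, float]:
    """(Accuracy, Sensitivity, Specificity) from confusion counts."""
    c = confusion
    if c.total == 0 or (c.tp + c.fn) == 0 or (c.tn + c.fp) == 0:
        raise ZeroDivisionError("metric denominator is zero for these counts")
    acc = (c.tp + c.tn) / c.total
    sen = c.tp / (c.tp + c.fn)
    spe = c.tn / (c.tn + c.fp)
    return acc, sen, spe


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (positive class = "A")."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes in the labels")
    return float(roc_auc_score(labels, scores))


def mean_metric(acc: float, sen: float, spe: float) -> float:
    """Arithmetic mean of accuracy, sensitivity and specificity."""
    return (acc + sen + spe) / 3.0


def postprocess(labels) -> np.ndarray:
    """Flip isolated interior labels in a single simultaneous pass.

    A 010 subsequence becomes 000 and a 101 becomes 111; both rewrites are
    decided on the *input* sequence, so the pass is applied exactly once and
    endpoints never change.
    """
    x = np.asarray(labels).astype(np.int8)
    if x.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    if len(x) < 3:
        return x.copy()
    out = x.copy()
    interior = (x[:-2] == x[2:]) & (x[1:-1] != x[:-2])
    out[1:-1][interior] = x[:-2][interior]
    return out


def diversity(population) -> float:
    """Normalized mean pairwise Hamming distance of a genome population.

    Div = (2 / (z L (z-1))) * sum_{mu<theta} Ham(p_mu, p_theta), in [0, 1].
    """
    pop = np.asarray(population)
    if pop.ndim != 2:
        raise ValueError("population must be a 2-D array of equal-length genomes")
    z, L = pop.shape
    if z < 2:
        raise ValueError("diversity needs at least two genomes")
    # pdist's hamming metric is already Ham/L; its mean over pairs is Div
    return float(pdist(pop, metric="hamming").mean())


# ---------------------------------------------------------------------------
# validation protocols


def _prepare(cohort: list[Recording], time_steps: int):
    """Preprocess every recording once and window it for the given T."""
    prepared = {}
    for rec in cohort:
        windows = make_windows(preprocess_recording(rec), time_steps)
        prepared[rec.subject_id] = windows_to_arrays(windows)
    return prepared


def _pool(prepared, subject_ids):
    X = np.concatenate([prepared[s][0] for s in subject_ids])
    y = np.concatenate([prepared[s][1] for s in subject_ids])
    return X, y


def split_two_folds(cohort: list[Recording], rng: np.random.Generator):
    """Random group-stratified split of subjects into two disjoint folds."""
    folds = ([], [])
    groups: dict[str, list[str]] = {}
    for rec in cohort:
        groups.setdefault(rec.group or "all", []).append(rec.subject_id)
    for members in groups.values():
        members = list(members)
        rng.shuffle(members)
        half = len(members) // 2
        folds[0].extend(members[:half])
        folds[1].extend(members[half:])
    if set(folds[0]) & set(folds[1]):
        raise RuntimeError("a subject appears in both folds")
    return folds


def tfcv_fitness(
    config: ModelConfig,
    cohort: list[Recording],
    hp: TrainingHyperparams,
    rng: np.random.Generator,
) -> float:
    """Two-fold cross-validated mean AUC — the optimizers' fitness (PM).

    Subjects are split into two subject-independent, group-stratified folds;
    a cold-started model is trained on each fold and scored on the other, and
    the two test AUCs are averaged.
    """
    if len(cohort) < 4:
        raise ValueError("TFCV needs at least 2 subjects per fold")
    prepared = _prepare(cohort, config.time_steps)
    fold_a, fold_b = split_two_folds(cohort, rng)
    aucs = []
    for train_ids, test_ids in ((fold_a, fold_b), (fold_b, fold_a)):
        model = build_model(config, seed=int(rng.integers(2**31)))
        train(model, _pool(prepared, train_ids), hp)
        X_test, y_test = _pool(prepared, test_ids)
        aucs.append(roc_auc(predict_scores(model, (X_test, None)), y_test))
    return float(np.mean(aucs))


def loo_evaluate(
    config: ModelConfig,
    cohort: list[Recording],
    hp: TrainingHyperparams,
    rng: np.random.Generator,
    return_models: bool = False,
):
    """Leave-one-subject-out assessment with a cold start per cycle.

    Every cycle trains on all other subjects from fresh random weights,
    selects the decision threshold on the training ROC, classifies the
    held-out subject, applies the isolated-label post-processing, and scores
    the result.
    """
    if len(cohort) < 3:
        raise ValueError("LOO needs at least 3 subjects")
    prepared = _prepare(cohort, config.time_steps)
    results: list[EvalResult] = []
    models: list[FusionModel] = []
    for rec in cohort:
        train_ids = [r.subject_id for r in cohort if r.subject_id != rec.subject_id]
        if rec.subject_id in train_ids:
            raise RuntimeError("test subject leaked into the training fold")
        X_train, y_train = _pool(prepared, train_ids)
        model = build_model(config, seed=int(rng.integers(2**31)))
        train(model, (X_train, y_train), hp)
        train_scores = predict_scores(model, (X_train, None))
        threshold = select_threshold(train_scores, y_train)
        X_test, y_test = prepared[rec.subject_id]
        scores = predict_scores(model, (X_test, None))
        y_pred = postprocess((scores >= threshold).astype(int))
        confusion = confusion_from_predictions(y_test, y_pred)
        acc, sen, spe = metrics(confusion)
        results.append(
            EvalResult(
                subject_id=rec.subject_id,
                confusion=confusion,
                acc=acc,
                sen=sen,
                spe=spe,
                auc=roc_auc(scores, y_test),
                threshold=threshold,
            )
        )
        if return_models:
            models.append(model)
    return (results, models) if return_models else results


def summarize_loo(results: list[EvalResult]) -> pd.DataFrame:
    """Per-metric mean, sd, min and max over the LOO cycles."""
    rows = {
        "Acc": [r.acc for r in results],
        "Sen": [r.sen for r in results],
        "Spe": [r.spe for r in results],
        "AUC": [r.auc for r in results],
    }
    return pd.DataFrame(
        {
            "mean": {k: np.mean(v) for k, v in rows.items()},
            "sd": {k: np.std(v, ddof=1) for k, v in rows.items()},
            "min": {k: np.min(v) for k, v in rows.items()},
            "max": {k: np.max(v) for k, v in rows.items()},
        }
    )
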