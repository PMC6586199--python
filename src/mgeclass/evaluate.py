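"""Evaluation artifacts: 3-class confusion matrices, one-vs-rest
TPR/FPR/AUC, threshold sweeps, and the derived life/trans scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .fragments import CLASS_TO_INDEX, CLASSES, ScoreTriple


def _strip_uncertain(label: str) -> tuple[str, bool]:
    if label.startswith("uncertain "):
        return label[len("uncertain "):], True
    return label, False


def confusion_matrix(truth: list[str], predicted: list[str],
                     uncertain: str = "exclude") -> np.ndarray:
    """3x3 counts; rows = true class, columns = predicted class, in the
    fixed order (phage, chromosome, plasmid).

    ``uncertain`` controls predictions carrying the "uncertain " prefix:
    "exclude" drops them, "map" counts them as their class component.
    """
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    if uncertain not in ("exclude", "map"):
        raise ValueError(f"uncertain must be 'exclude' or 'map', got {uncertain!r}")
    mat = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(truth, predicted):
        cls, was_uncertain = _strip_uncertain(p)
        if was_uncertain and uncertain == "exclude":
            continue
        if t not in CLASS_TO_INDEX or cls not in CLASS_TO_INDEX:
            raise ValueError(f"label outside the 3 classes: {t!r} / {p!r}")
        mat[CLASS_TO_INDEX[t], CLASS_TO_INDEX[cls]] += 1
    return mat


def format_confusion_matrix(mat: np.ndarray) -> str:
    width = max(len(c) for c in CLASSES) + 2
    lines = [" " * width + "".join(f"{c:>{width}}" for c in CLASSES)]
    for i, cls in enumerate(CLASSES):
        lines.append(f"{cls:>{width}}"
                     + "".join(f"{mat[i, j]:>{width}}" for j in range(3)))
    return "\n".join(lines)


@dataclass
class ClassMetrics:
    positive_class: str
    tpr: float
    fpr: float
    auc: float


def one_vs_rest_metrics(truth: list[str],
                        scores: list[ScoreTriple] | np.ndarray,
                        positive_class: str) -> ClassMetrics:
    """TPR/FPR from argmax labels and ROC AUC from the positive class's
    score against all other fragments (Mann-Whitney tie handling)."""
    if positive_class not in CLASS_TO_INDEX:
        raise ValueError(f"unknown class {positive_class!r}")
    arr = _score_array(scores)
    y_true = np.array([t == positive_class for t in truth])
    if y_true.all() or not y_true.any():
        raise ValueError("need both positive and negative fragments for AUC")
    pred_idx = arr.argmax(axis=1)
    pred_pos = pred_idx == CLASS_TO_INDEX[positive_class]
    tp = int((y_true & pred_pos).sum())
    fn = int((y_true & ~pred_pos).sum())
    fp = int((~y_true & pred_pos).sum())
    tn = int((~y_true & ~pred_pos).sum())
    auc = float(roc_auc_score(y_true, arr[:, CLASS_TO_INDEX[positive_class]]))
    return ClassMetrics(positive_class=positive_class,
                        tpr=tp / (tp + fn), fpr=fp / (tn + fp), auc=auc)


def threshold_sweep(truth: list[str], scores: list[ScoreTriple] | np.ndarray,
                    thresholds: list[float]) -> pd.DataFrame:
    """Uncertain rate and metrics on the certain subset per threshold.

    Rows where every fragment is uncertain carry NaN metrics.
    """
    arr = _score_array(scores)
    truth_idx = np.array([CLASS_TO_INDEX[t] for t in truth])
    pred_idx = arr.argmax(axis=1)
    max_score = arr.max(axis=1)
    rows = []
    for thr in thresholds:
        if not 0 <= thr <= 1:
            raise ValueError(f"threshold must be in [0, 1], got {thr}")
        certain = max_score >= thr
        rate = float(1 - certain.mean())
        if not certain.any():
            rows.append({"threshold": thr, "uncertain_rate": rate,
                         "accuracy": np.nan, "tpr_phage": np.nan,
                         "fpr_phage": np.nan})
            continue
        acc = float((pred_idx[certain] == truth_idx[certain]).mean())
        pos = truth_idx[certain] == 0
        hit = pred_idx[certain] == 0
        tpr = float((pos & hit).sum() / pos.sum()) if pos.any() else np.nan
        neg = ~pos
        fpr = float((neg & hit).sum() / neg.sum()) if neg.any() else np.nan
        rows.append({"threshold": thr, "uncertain_rate": rate,
                     "accuracy": acc, "tpr_phage": tpr, "fpr_phage": fpr})
    return pd.DataFrame(rows)


@dataclass
class DerivedScores:
    """Normalized score contrasts: (phage - chromosome)/phage and
    (plasmid - chromosome)/plasmid."""

    life_score: float
    trans_score: float
    life_defined: bool
    trans_defined: bool


def derived_scores(scores: ScoreTriple) -> DerivedScores:
    life_defined = scores.phage != 0
    trans_defined = scores.plasmid != 0
    life = ((scores.phage - scores.chromosome) / scores.phage
            if life_defined else float("nan"))
    trans = ((scores.plasmid - scores.chromosome) / scores.plasmid
             if trans_defined else float("nan"))
    return DerivedScores(life_score=life, trans_score=trans,
                         life_defined=life_defined,
                         trans_defined=trans_defined)


def _score_array(scores) -> np.ndarray:
    if isinstance(scores, np.ndarray):
        return scores
    return np.array([s.as_tuple() for s in scores], dtype=np.float64)
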