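"""Training wrapper and evaluation statistics.

Slide scores are probabilities in [0, 1].  Evaluation follows standard
clinical-ML reporting: AUROC (Mann-Whitney form, ties get half credit) with
a 95% confidence interval from DeLong's structural-component variance, a
discrimination threshold chosen on the validation set by Youden's J, and
accuracy / precision / recall / F1 at that threshold, where a score counts
as positive iff it is strictly greater than the threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .dsmil_head import MILOutput
from .errors import DataError, DegenerateWarning
from .model import DTDSMILClassifier


@dataclass
class TrainConfig:
    epochs: int = 20
    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    seed: int = 0
    loss_mode: str = "dual_bce"
    optimizer: str = "adam"

    def __post_init__(self):
        if self.epochs < 1:
            raise DataError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise DataError("learning_rate must be >= 0")
        if self.optimizer != "adam":
            raise DataError("only the adam optimizer is implemented")


@dataclass
class EvalReport:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    threshold: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    n_pos: int
    n_neg: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([asdict(self)]).to_csv(path, index=False)


def _binary_loss(c_max: float, c_slide: float, c: float, label: int,
                 mode: str) -> float:
    eps = 1e-12

    def bce(p):
        p = min(max(p, eps), 1.0 - eps)
        return -np.log(p) if label else -np.log(1.0 - p)

    if mode == "dual_bce":
        return 0.5 * (bce(c_max) + bce(c_slide))
    if mode == "fused_bce":
        return bce(c)
    raise DataError(f"unknown loss mode {mode!r}")


def loss(output: MILOutput, label: int, mode: str = "dual_bce") -> float:
    """Bag-level binary cross-entropy of one MIL output."""
    return float(_binary_loss(output.c_max, output.c_slide, output.c,
                              int(label), mode))


def train(bags, labels, model_cfgs: dict | None = None,
          train_cfg: TrainConfig | None = None):
    """Fit a :class:`DTDSMILClassifier`; returns (model, loss history)."""
    train_cfg = train_cfg or TrainConfig()
    model_cfgs = dict(model_cfgs or {})
    model = DTDSMILClassifier(
        epochs=train_cfg.epochs, learning_rate=train_cfg.learning_rate,
        weight_decay=train_cfg.weight_decay, loss_mode=train_cfg.loss_mode,
        random_state=train_cfg.seed, **model_cfgs)
    model.fit(bags, labels)
    return model, model.history_


# -- ROC / AUC ------------------------------------------------------------

def _check_two_class(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    neg = labels == 0
    if pos.sum() == 0 or neg.sum() == 0:
        raise DataError("both classes must be present")
    return pos, neg


def roc_auc(scores, labels) -> float:
    """AUROC as the Mann-Whitney statistic; ties receive half credit."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_class(labels)
    ranks = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation AUC confidence interval via DeLong's method.

    Uses the structural components (placement values) of the positive and
    negative score sets; the interval is clipped to [0, 1].  When the
    empirical variance is zero (e.g. perfect separation) the interval
    collapses to the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_class(labels)
    if pos.sum() < 2 or neg.sum() < 2:
        raise DataError("DeLong CI needs at least two scores per class")
    x, y = scores[pos], scores[neg]  # positives, negatives
    m, n = len(x), len(y)
    all_ranks = rankdata(np.concatenate([x, y]))
    v10 = (all_ranks[:m] - rankdata(x)) / n          # placement of positives
    v01 = 1.0 - (all_ranks[m:] - rankdata(y)) / m    # placement of negatives
    auc = float(v10.mean())
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    if var <= 0.0:
        return auc, auc
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0))


def choose_threshold(val_scores, val_labels, rule: str = "youden") -> float:
    """Validation-set threshold maximizing Youden's J = sens + spec - 1.

    Candidate cuts are midpoints between consecutive distinct scores plus
    the extremes; ties are resolved toward the smallest threshold.  If all
    scores are identical the (degenerate) common value is returned.
    """
    if rule != "youden":
        raise DataError(f"unknown threshold rule {rule!r}")
    scores = np.asarray(val_scores, dtype=float)
    pos, neg = _check_two_class(val_labels)
    distinct = np.unique(scores)
    if len(distinct) == 1:
        warnings.warn("all validation scores identical; threshold degenerate",
                      DegenerateWarning, stacklevel=2)
        return float(distinct[0])
    candidates = np.concatenate([
        [distinct[0] - 0.5],                    # everything positive
        (distinct[:-1] + distinct[1:]) / 2.0,   # interior cuts
        [distinct[-1]],                         # nothing positive (strict >)
    ])
    n_pos, n_neg = pos.sum(), neg.sum()
    best_t, best_j = None, -np.inf
    for t in candidates:  # ascending, so first max is the smallest threshold
        pred = scores > t
        j = (pred[pos].sum() / n_pos) - (pred[neg].sum() / n_neg)
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


def confusion_metrics(scores, labels, threshold: float) -> dict:
    """Accuracy/precision/recall/F1 with strictly-greater positivity."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    undefined_precision = (tp + fp) == 0
    if undefined_precision:
        warnings.warn("no predicted positives; precision reported as 0",
                      DegenerateWarning, stacklevel=2)
    precision = 0.0 if undefined_precision else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = (0.0 if precision + recall == 0
          else 2 * precision * recall / (precision + recall))
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "accuracy": (tp + tn) / len(labels),
        "precision": precision, "recall": recall, "f1": f1,
        "precision_undefined": undefined_precision,
    }


def evaluate_scores(scores, labels, threshold: float) -> EvalReport:
    """Assemble the full evaluation report at a given threshold."""
    pos, neg = _check_two_class(labels)
    cm = confusion_metrics(scores, labels, threshold)
    auc = roc_auc(scores, labels)
    try:
        lo, hi = delong_ci(scores, labels)
    except DataError:  # fewer than two scores in a class: no CI
        lo, hi = auc, auc
    return EvalReport(auc=auc, auc_ci_low=lo, auc_ci_high=hi,
                      threshold=float(threshold), accuracy=cm["accuracy"],
                      precision=cm["precision"], recall=cm["recall"],
                      f1=cm["f1"], n_pos=int(pos.sum()), n_neg=int(neg.sum()))


def save_slide_scores(path: str | Path, slide_ids, outputs, labels,
                      threshold: float) -> None:
    rows = []
    for sid, out, lab in zip(slide_ids, outputs, labels):
        rows.append({"slide_id": sid, "c": out.c, "c_max": out.c_max,
                     "c_slide": out.c_slide, "label": int(lab),
                     "pred": int(out.c > threshold)})
    pd.DataFrame(rows).to_csv(path, index=False)
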