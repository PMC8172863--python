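"""Metrics and experiment harness.

Classification quality is scored with macro-averaged F1, argmax accuracy,
multiclass log loss and macro one-vs-rest AUC.  The regime-comparison
harness contrasts three training conditions on one dataset: a plain GP
classifier on gold labels, the same classifier on per-instance majority-vote
labels, and the crowd model on the raw annotations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

from .crowd import AnnotationSet
from .model import FitConfig, fit, fit_svgp, predict
from .patches import LabelMask, dice
from .simulate import CrowdDataset

log = logging.getLogger(__name__)


@dataclass
class MetricReport:
    """Headline classification metrics plus per-class breakdowns."""

    f1: float
    accuracy: float
    log_loss: float
    auc: float
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "f1": self.f1,
            "accuracy": self.accuracy,
            "log_loss": self.log_loss,
            "auc": self.auc,
            "per_class": self.per_class,
            "averaging": "macro (F1), one-vs-rest macro (AUC)",
        }


def classification_metrics(probs: np.ndarray, true_labels: np.ndarray) -> MetricReport:
    """Score predicted class probabilities against true labels in 1..K.

    Accuracy uses the argmax rule (ties -> smallest class index); F1 is
    macro-averaged; log loss is -mean log p(true class); AUC is one-vs-rest,
    macro-averaged over the classes present in ``true_labels`` (absent
    classes are excluded with a warning).
    """
    probs = np.asarray(probs, dtype=float)
    true_labels = np.asarray(true_labels, dtype=int)
    if probs.shape[0] != true_labels.shape[0]:
        raise ValueError("probs and true_labels must have matching length")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of probs must sum to 1")
    K = probs.shape[1]
    pred = np.argmax(probs, axis=1) + 1
    accuracy = float(np.mean(pred == true_labels))
    all_classes = np.arange(1, K + 1)
    f1_per = f1_score(
        true_labels, pred, labels=all_classes, average=None, zero_division=0.0
    )
    f1_macro = float(np.mean(f1_per))
    p_true = np.clip(probs[np.arange(len(true_labels)), true_labels - 1], 1e-15, 1.0)
    logloss = float(-np.mean(np.log(p_true)))
    present = np.unique(true_labels)
    aucs: dict[int, float] = {}
    for k in all_classes:
        if k not in present or present.size < 2:
            warnings.warn(
                f"class {k} has no positive or no negative examples; "
                "excluded from AUC",
                stacklevel=2,
            )
            continue
        aucs[int(k)] = float(roc_auc_score(true_labels == k, probs[:, k - 1]))
    auc_macro = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    per_class = {
        int(k): {"f1": float(f1_per[k - 1]), "auc": aucs.get(int(k))}
        for k in all_classes
    }
    return MetricReport(f1_macro, accuracy, logloss, auc_macro, per_class)


def majority_vote_labels(Y: AnnotationSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-instance modal annotation (ties -> smallest class index).

    Returns (instance_ids, labels); only annotated instances appear.
    """
    ids = Y.annotated_instances
    votes = np.zeros((ids.size, Y.n_classes), dtype=int)
    row_of = {int(i): r for r, i in enumerate(ids)}
    for i, lab in zip(Y.instance_ids, Y.label_index):
        votes[row_of[int(i)], lab] += 1
    return ids, np.argmax(votes, axis=1) + 1


def run_regime_comparison(
    dataset: CrowdDataset,
    config: FitConfig | None = None,
    test_fraction: float = 0.3,
    split_seed: int = 0,
    mc_samples: int = 100,
) -> pd.DataFrame:
    """Train under three label regimes and evaluate on one shared test split.

    Regimes: ``gold`` (plain GP on true labels), ``majority_vote`` (plain GP
    on per-instance modal annotations) and ``crowdsourced`` (crowd model on
    the raw annotation table).  Returns a tidy metric table indexed by
    regime.
    """
    config = config or FitConfig()
    train, X_test, y_test = dataset.train_test_split(test_fraction, split_seed)
    K = dataset.n_classes
    if train.annotations.annotated_instances.size == 0:
        raise ValueError("regime 'crowdsourced' has no training annotations")

    models = {}
    models["gold"] = fit_svgp(train.X, train.true_labels, config, n_classes=K)
    mv_ids, mv_labels = majority_vote_labels(train.annotations)
    full_mv = np.zeros(train.X.shape[0], dtype=int)
    full_mv[mv_ids] = mv_labels
    if np.any(full_mv == 0):
        # instances nobody labeled are excluded from MV training
        keep = full_mv > 0
        models["majority_vote"] = fit_svgp(
            train.X[keep], full_mv[keep], config, n_classes=K
        )
    else:
        models["majority_vote"] = fit_svgp(train.X, full_mv, config, n_classes=K)
    models["crowdsourced"] = fit(train.X, train.annotations, config, n_classes=K)

    rows = []
    for regime, model in models.items():
        probs = predict(model, X_test, mc_samples=mc_samples, seed=config.seed)
        rep = classification_metrics(probs, y_test)
        rows.append(
            {
                "regime": regime,
                "f1": rep.f1,
                "accuracy": rep.accuracy,
                "log_loss": rep.log_loss,
                "auc": rep.auc,
            }
        )
    return pd.DataFrame(rows).set_index("regime")


def _overall_dice(pred: LabelMask, ref: LabelMask, n_classes: int) -> float:
    """Micro DICE over classes 1..K: 2 sum_k |P_k ∩ R_k| / sum_k (|P_k|+|R_k|)."""
    num = 0
    den = 0
    for k in range(1, n_classes + 1):
        p = pred.grid == k
        r = ref.grid == k
        num += int(np.logical_and(p, r).sum())
        den += int(p.sum()) + int(r.sum())
    return 2.0 * num / den if den else 1.0


def annotator_agreement_report(
    model,
    feature_provider,
    annotator_masks: dict[int, list[LabelMask]],
    expert_masks: list[LabelMask] | None = None,
    patch_size: int = 8,
    overlap: float = 0.95,
    mc_samples: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """DICE agreement between annotator-specific dense inferences and each
    annotator's held-out masks, with a 95% normal CI over annotators.

    Annotator rows use ``predict_annotator``; the optional ground-truth row
    (compared against expert masks) uses ``predict``.  Annotators without
    test masks are skipped with a warning.
    """
    from .patches import dense_prediction

    K = model.n_classes
    rows = []
    for a in sorted(annotator_masks):
        masks = annotator_masks[a]
        if not masks:
            warnings.warn(f"annotator {a} has no test annotations; skipped")
            continue
        per_class = np.zeros(K)
        overall = 0.0
        for ref in masks:
            dense = dense_prediction(
                model,
                feature_provider,
                ref.shape,
                patch_size,
                overlap,
                mc_samples=mc_samples,
                annotator=a,
            )
            for k in range(1, K + 1):
                per_class[k - 1] += dice(dense, ref, k)
            overall += _overall_dice(dense, ref, K)
        rows.append(
            {
                "annotator": a,
                **{f"dice_class_{k}": per_class[k - 1] / len(masks) for k in range(1, K + 1)},
                "dice_overall": overall / len(masks),
            }
        )
    table = pd.DataFrame(rows)
    summary: dict = {}
    if len(table):
        vals = table["dice_overall"].to_numpy()
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        half = 1.96 * sd / np.sqrt(vals.size)
        summary["participants"] = {"mean": mean, "ci95_halfwidth": float(half)}
    if expert_masks:
        per_class = np.zeros(K)
        overall = 0.0
        for ref in expert_masks:
            dense = dense_prediction(
                model, feature_provider, ref.shape, patch_size, overlap,
                mc_samples=mc_samples,
            )
            for k in range(1, K + 1):
                per_class[k - 1] += dice(dense, ref, k)
            overall += _overall_dice(dense, ref, K)
        summary["ground_truth"] = {
            "dice_overall": overall / len(expert_masks),
            **{
                f"dice_class_{k}": per_class[k - 1] / len(expert_masks)
                for k in range(1, K + 1)
            },
        }
    return table, summary
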