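"""Dual-level evaluation metrics for three-class subject-independent decoding.

Binary metrics are extended one-vs-rest (OvR): for each class *i* the counts
TP_i, FP_i, FN_i, TN_i come from treating *i* as positive. Accuracy is the
global fraction correct; precision, recall and F1 use weighted averaging
(class weight = its true support). Cohen's kappa corrects agreement for
chance: kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
p_e the chance agreement from the confusion-matrix marginals. Everything is
reported at both the trial level and the subject level (after majority-vote
aggregation), because the two levels answer different questions and neither
is derivable from the other when trial counts differ across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CLASSES


def confusion_matrix(y_true, y_pred, classes: tuple[str, ...] = CLASSES) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    idx = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred, strict=True):
        m[idx[str(t)], idx[str(p)]] += 1
    return m


def ovr_counts(conf: np.ndarray) -> list[dict[str, int]]:
    """Per-class one-vs-rest TP/FP/FN/TN from a square confusion matrix."""
    total = conf.sum()
    out = []
    for i in range(conf.shape[0]):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        out.append({"TP": int(tp), "FP": int(fp), "FN": int(fn),
                    "TN": int(total - tp - fp - fn)})
    return out


def cohen_kappa(conf: np.ndarray) -> float:
    """Chance-corrected agreement from a confusion matrix of counts."""
    conf = np.asarray(conf, dtype=float)
    if np.any(conf < 0):
        raise ValueError("negative counts")
    total = conf.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(conf) / total
    p_e = float(np.sum(conf.sum(axis=1) * conf.sum(axis=0))) / total**2
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0  # degenerate single-cell table, perfect agreement
        raise ValueError("kappa undefined: chance agreement is 1 without perfect agreement")
    return float((p_o - p_e) / (1.0 - p_e))


def _prf(conf: np.ndarray) -> dict[str, float]:
    """Accuracy plus weighted and macro precision/recall/F1, as fractions."""
    conf = np.asarray(conf, dtype=float)
    total = conf.sum()
    support = conf.sum(axis=1)
    pred_pos = conf.sum(axis=0)
    tp = np.diag(conf)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / pred_pos, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    weights = support / total
    present = support > 0
    return {
        "accuracy": float(tp.sum() / total),
        "precision_weighted": float(np.sum(weights * precision)),
        "recall_weighted": float(np.sum(weights * recall)),
        "f1_weighted": float(np.sum(weights * f1)),
        "precision_macro": float(precision[present].mean()),
        "recall_macro": float(recall[present].mean()),
        "f1_macro": float(f1[present].mean()),
    }


@dataclass
class MetricsReport:
    """Trial- and subject-level metrics of one LOSO evaluation."""

    classes: tuple[str, ...]
    trial_confusion: np.ndarray
    subject_confusion: np.ndarray
    trial_metrics: dict[str, float] = field(default_factory=dict)
    subject_metrics: dict[str, float] = field(default_factory=dict)
    trial_ovr: list[dict] = field(default_factory=list)
    subject_ovr: list[dict] = field(default_factory=list)
    trial_kappa: float = float("nan")
    subject_kappa: float = float("nan")

    def to_dict(self) -> dict:
        pct = lambda d: {k: 100.0 * v for k, v in d.items()}
        return {
            "classes": list(self.classes),
            "trial_level": {
                "confusion": self.trial_confusion.tolist(),
                "ovr_counts": self.trial_ovr,
                "kappa": self.trial_kappa,
                **pct(self.trial_metrics),
            },
            "subject_level": {
                "confusion": self.subject_confusion.tolist(),
                "ovr_counts": self.subject_ovr,
                "kappa": self.subject_kappa,
                **pct(self.subject_metrics),
            },
        }

    def summary(self) -> str:
        rows = []
        head = f"{'metric':<22}{'trial level':>14}{'subject level':>16}"
        rows.append(head)
        rows.append("-" * len(head))
        for key, label in [
            ("accuracy", "accuracy (%)"),
            ("precision_weighted", "precision, wtd (%)"),
            ("recall_weighted", "recall, wtd (%)"),
            ("f1_weighted", "F1, wtd (%)"),
        ]:
            rows.append(f"{label:<22}{100 * self.trial_metrics[key]:>14.2f}"
                        f"{100 * self.subject_metrics[key]:>16.2f}")
        rows.append(f"{'Cohen kappa':<22}{self.trial_kappa:>14.3f}{self.subject_kappa:>16.3f}")
        rows.append("")
        rows.append("subject-level confusion (rows=true, cols=pred): "
                    + "/".join(self.classes))
        for r in self.subject_confusion:
            rows.append("  " + " ".join(f"{v:4d}" for v in r))
        return "\n".join(rows)


def compute_metrics(
    trial_true,
    trial_pred,
    subject_true,
    subject_pred,
    classes: tuple[str, ...] = CLASSES,
) -> MetricsReport:
    """Assemble the dual-level report from per-trial and per-subject labels."""
    if len(subject_true) != len(subject_pred):
        raise ValueError("subject truth/prediction length mismatch")
    tc = confusion_matrix(trial_true, trial_pred, classes)
    sc = confusion_matrix(subject_true, subject_pred, classes)
    return MetricsReport(
        classes=classes,
        trial_confusion=tc,
        subject_confusion=sc,
        trial_metrics=_prf(tc),
        subject_metrics=_prf(sc),
        trial_ovr=ovr_counts(tc),
        subject_ovr=ovr_counts(sc),
        trial_kappa=cohen_kappa(tc),
        subject_kappa=cohen_kappa(sc),
    )
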