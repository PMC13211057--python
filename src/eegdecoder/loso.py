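"""Nested leave-one-subject-out (LOSO) evaluation.

Outer loop: every subject is held out exactly once; the remaining N-1
subjects form the development set. Inner loop: the development subjects are
partitioned (subject-level, class-stratified) into 5 folds; for each fold a
model is trained on the other 4 folds — with per-channel normalization
fitted on those training trials only — and validated on the held-out fold
with early stopping on validation accuracy. The single model with the best
validation accuracy across the 5 inner folds, together with its normalizer,
is applied to the held-out subject's trials, and the subject receives the
majority-vote label over its trials (ties broken by the larger summed class
score).

Subject leakage is impossible by construction and additionally asserted at
runtime: the held-out subject's trials are never touched before testing.

The experiment surface follows the model/results idiom: build a
:class:`LOSOExperiment` from a :class:`~eegdecoder.io.TrialSet`, call
``fit()``, and read estimates and diagnostics off the returned
:class:`LOSOResults`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import CLASSES, TrialSet
from .metrics import MetricsReport, compute_metrics
from .model import (
    EEGNetConfig,
    ModelConfig,
    build_model,
    count_parameters,
)
from .nn import Adam, Network, softmax_cross_entropy
from .preprocess import NormParams, apply_normalizer, fit_channel_normalizer

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization protocol: Adam, lr 1e-3, weight decay 1e-4, batches of
    64, at most 30 epochs with patience-10 early stopping on validation
    accuracy, 5 subject-level inner folds, default seed 2025."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 30
    early_stop_patience: int = 10
    inner_folds: int = 5
    seed: int = 2025
    seed_set: tuple[int, ...] = (42, 99, 123, 2025, 2026)

    def __post_init__(self) -> None:
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("rates and sizes must be positive")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def make_loso_splits(subject_ids) -> list[tuple[list[str], str]]:
    """One (train_subjects, test_subject) split per subject, in input order."""
    subjects = [str(s) for s in subject_ids]
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids")
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    return [([s for s in subjects if s != held], held) for held in subjects]


def make_inner_folds(
    train_subjects,
    labels_by_subject: dict[str, str],
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> list[list[str]]:
    """Subject-level partition into k folds, class-stratified.

    Fold sizes differ by at most one; within every class the per-fold counts
    also differ by at most one (subjects of each class are dealt in shuffled
    order to the currently smallest folds).
    """
    subjects = [str(s) for s in train_subjects]
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects cannot fill {k} folds")
    rng = rng or np.random.default_rng()
    folds: list[list[str]] = [[] for _ in range(k)]
    by_class: dict[str, list[str]] = {}
    for s in subjects:
        by_class.setdefault(labels_by_subject[s], []).append(s)
    for label in sorted(by_class):
        members = sorted(by_class[label])
        rng.shuffle(members)
        # deal this class cyclically starting from the smallest folds
        order = sorted(range(k), key=lambda i: (len(folds[i]), i))
        for j, s in enumerate(members):
            folds[order[j % k]].append(s)
    return folds


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _encode_labels(labels, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    return np.array([idx[str(l)] for l in labels], dtype=np.int64)


def predict_scores(net: Network, ts: TrialSet, batch_size: int = 128) -> np.ndarray:
    """Eval-mode class scores for every trial."""
    out = []
    for i in range(0, ts.n_trials, batch_size):
        out.append(net.forward(ts.trials[i : i + batch_size], training=False))
    return np.concatenate(out) if out else np.empty((0, 3), dtype=np.float32)


def train_model(
    net: Network,
    train: TrialSet,
    val: TrialSet,
    tc: TrainConfig,
    classes: tuple[str, ...] = CLASSES,
) -> tuple[Network, list[dict]]:
    """Seeded Adam training with early stopping on validation accuracy.

    Returns the network restored to its best-validation-epoch weights plus
    the per-epoch history. Training and validation sets must already be
    normalized (train-fitted) and subject-disjoint.
    """
    if train.n_trials == 0 or val.n_trials == 0:
        raise ValueError("empty training or validation set")
    train_subj = set(train.subjects())
    val_subj = set(val.subjects())
    if train_subj & val_subj:
        raise AssertionError(f"subject leakage into validation: {train_subj & val_subj}")

    rng = np.random.default_rng(tc.seed)
    net.set_rng(rng)
    y_train = _encode_labels(train.labels, classes)
    y_val = _encode_labels(val.labels, classes)
    opt = Adam(net.parameters(), lr=tc.learning_rate, weight_decay=tc.weight_decay)

    best_state: dict | None = None
    best_acc = -np.inf
    best_key: tuple | None = None
    best_epoch = -1
    history: list[dict] = []
    n = train.n_trials
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        t0 = time.perf_counter()
        for i in range(0, n, tc.batch_size):
            sel = order[i : i + tc.batch_size]
            opt.zero_grad()
            scores = net.forward(train.trials[sel], training=True)
            loss, grad = softmax_cross_entropy(scores, y_train[sel])
            net.backward(grad)
            opt.step()
            net.apply_constraints()
            epoch_loss += loss * len(sel)
        val_scores = predict_scores(net, val)
        val_loss, _ = softmax_cross_entropy(val_scores, y_val)
        val_acc = float(np.mean(val_scores.argmax(axis=1) == y_val))
        history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / n,
            "val_acc": val_acc,
            "val_loss": val_loss,
            "seconds": time.perf_counter() - t0,
        })
        if val_acc > best_acc:
            best_acc = val_acc
            best_epoch = epoch  # patience counts from accuracy improvements
        # stored weights rank by (accuracy, then lower loss): small
        # subject-level validation folds saturate accuracy immediately,
        # and the cross-entropy still ranks later epochs
        key = (val_acc, -val_loss)
        if best_key is None or key > best_key:
            best_key = key
            best_state = net.state_dict()
        if epoch - best_epoch >= tc.early_stop_patience:
            break
    if best_state is not None:
        net.load_state_dict(best_state)
    history_meta = {"best_epoch": best_epoch, "best_val_acc": best_acc,
                    "best_val_loss": -best_key[1]}
    for h in history:
        h.update({k: v for k, v in history_meta.items()})
    return net, history


def majority_vote(
    trial_labels,
    trial_scores: np.ndarray | None = None,
    classes: tuple[str, ...] = CLASSES,
) -> str:
    """Modal predicted label; ties broken by the larger summed class score."""
    labels = [str(l) for l in trial_labels]
    if not labels:
        raise ValueError("majority vote over zero trials")
    counts = {c: labels.count(c) for c in classes if c in labels}
    top = max(counts.values())
    tied = [c for c, v in counts.items() if v == top]
    if len(tied) == 1 or trial_scores is None:
        return tied[0]
    sums = {}
    for c in tied:
        ci = classes.index(c)
        sums[c] = float(np.sum(np.asarray(trial_scores)[:, ci]))
    return max(sums, key=lambda c: (sums[c], -classes.index(c)))


# ---------------------------------------------------------------------------
# the nested protocol
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    held_out_subject: str
    true_label: str
    trial_pred: list[str]
    trial_scores: np.ndarray
    subject_pred: str
    selected_inner_fold: int
    inner_val_accs: list[float]
    history: list[dict]


@dataclass
class LOSOResult:
    folds: list[FoldResult]
    classes: tuple[str, ...]
    architecture: str
    train_config: TrainConfig

    def subject_truth(self) -> list[str]:
        return [f.true_label for f in self.folds]

    def subject_pred(self) -> list[str]:
        return [f.subject_pred for f in self.folds]

    def trial_truth(self) -> list[str]:
        return [f.true_label for f in self.folds for _ in f.trial_pred]

    def trial_pred(self) -> list[str]:
        return [p for f in self.folds for p in f.trial_pred]


def run_loso(
    dataset: TrialSet,
    architecture: str = "eegdecoder",
    model_config: ModelConfig | EEGNetConfig | None = None,
    train_config: TrainConfig | None = None,
    classes: tuple[str, ...] = CLASSES,
    progress: bool = False,
    checkpoint_dir=None,
) -> LOSOResult:
    """Run the full nested LOSO protocol on a labelled TrialSet.

    With ``checkpoint_dir`` set, the selected (best-validation) model of
    every outer fold is saved there together with its normalizer, one
    checkpoint per held-out subject.
    """
    tc = train_config or TrainConfig()
    if dataset.labels is None:
        raise ValueError("LOSO needs labelled trials")
    subjects = dataset.subjects()
    labels_by_subject = {s: dataset.subject_label(s) for s in subjects}
    splits = make_loso_splits(subjects)
    fold_rng = np.random.default_rng(tc.seed)

    folds: list[FoldResult] = []
    for outer_idx, (train_subjects, held_out) in enumerate(splits):
        assert held_out not in train_subjects
        inner = make_inner_folds(train_subjects, labels_by_subject,
                                 k=tc.inner_folds, rng=fold_rng)
        for f in inner:
            assert held_out not in f, "held-out subject leaked into an inner fold"

        best: tuple[float, dict, NormParams, int] | None = None
        inner_accs: list[float] = []
        best_history: list[dict] = []
        for i, val_fold in enumerate(inner):
            tr_subjects = [s for f in inner[:i] + inner[i + 1:] for s in f]
            train_ts = dataset.select_subjects(tr_subjects)
            val_ts = dataset.select_subjects(val_fold)
            norm = fit_channel_normalizer(train_ts)
            net = build_model(architecture, seed=tc.seed, model_config=model_config)
            net, history = train_model(
                net, apply_normalizer(train_ts, norm), apply_normalizer(val_ts, norm),
                tc, classes=classes,
            )
            acc = history[-1]["best_val_acc"]
            inner_accs.append(acc)
            # accuracy ties prefer lower validation loss, then the larger
            # (more informative) validation fold
            rank = (acc, -history[-1]["best_val_loss"], len(val_fold))
            if best is None or rank > best[0]:
                best = (rank, net.state_dict(), norm, i)
                best_history = history
            if progress:
                logger.info("outer %d/%d (%s) inner %d: val acc %.3f",
                            outer_idx + 1, len(splits), held_out, i, acc)

        _rank, state, norm, sel = best
        net = build_model(architecture, seed=tc.seed, model_config=model_config)
        net.load_state_dict(state)
        if checkpoint_dir is not None:
            from .deploy import save_checkpoint

            ckpt_dir = Path(checkpoint_dir)
            ckpt_dir.mkdir(parents=True, exist_ok=True)
            save_checkpoint(net, ckpt_dir / f"model_{held_out}.npz",
                            extra_arrays={"norm.mean": norm.mean, "norm.std": norm.std})
        test_ts = apply_normalizer(dataset.select_subjects([held_out]), norm)
        scores = predict_scores(net, test_ts)
        pred_idx = scores.argmax(axis=1)
        trial_pred = [classes[i] for i in pred_idx]
        subject_pred = majority_vote(trial_pred, scores, classes)
        folds.append(FoldResult(
            held_out_subject=held_out,
            true_label=labels_by_subject[held_out],
            trial_pred=trial_pred,
            trial_scores=scores,
            subject_pred=subject_pred,
            selected_inner_fold=sel,
            inner_val_accs=inner_accs,
            history=best_history,
        ))
        if progress:
            logger.info("outer %d/%d: %s true=%s pred=%s",
                        outer_idx + 1, len(splits), held_out,
                        labels_by_subject[held_out], subject_pred)
    return LOSOResult(folds=folds, classes=classes,
                      architecture=architecture, train_config=tc)


# ---------------------------------------------------------------------------
# model/results surface
# ---------------------------------------------------------------------------

class LOSOExperiment:
    """A subject-independent classification experiment on a TrialSet.

    Parameters
    ----------
    dataset : TrialSet
        Labelled trials for all subjects.
    architecture : {"eegdecoder", "eegnet"}
    model_config, train_config : optional overrides of the defaults.

    ``fit(seed=...)`` executes the nested LOSO protocol and returns a
    :class:`LOSOResults` with metrics, per-fold predictions and a summary
    table.
    """

    def __init__(
        self,
        dataset: TrialSet,
        architecture: str = "eegdecoder",
        model_config: ModelConfig | EEGNetConfig | None = None,
        train_config: TrainConfig | None = None,
        classes: tuple[str, ...] = CLASSES,
    ):
        if dataset.labels is None:
            raise ValueError("experiment needs labelled trials")
        self.dataset = dataset
        self.architecture = architecture
        self.model_config = model_config
        self.train_config = train_config or TrainConfig()
        self.classes = classes

    @classmethod
    def from_directory(cls, trial_dir, **kwargs) -> "LOSOExperiment":
        from .io import load_trialset

        return cls(load_trialset(trial_dir), **kwargs)

    def fit(self, seed: int | None = None, progress: bool = False,
            checkpoint_dir=None) -> "LOSOResults":
        tc = self.train_config
        if seed is not None:
            tc = TrainConfig(**{**asdict(tc), "seed": seed,
                                "seed_set": tuple(tc.seed_set)})
        t0 = time.perf_counter()
        result = run_loso(self.dataset, self.architecture, self.model_config,
                          tc, classes=self.classes, progress=progress,
                          checkpoint_dir=checkpoint_dir)
        metrics = compute_metrics(
            result.trial_truth(), result.trial_pred(),
            result.subject_truth(), result.subject_pred(),
            classes=self.classes,
        )
        return LOSOResults(self, result, metrics, time.perf_counter() - t0)

    def fit_seed_set(self, seeds: tuple[int, ...] | None = None,
                     progress: bool = False) -> "SeedRobustness":
        """Repeat the full LOSO under several seeds; report mean +/- sd."""
        seeds = tuple(seeds or self.train_config.seed_set)
        runs = [self.fit(seed=s, progress=progress) for s in seeds]
        return SeedRobustness(seeds, runs)


@dataclass
class LOSOResults:
    """Fitted-experiment results: predictions, metrics, diagnostics."""

    experiment: LOSOExperiment
    result: LOSOResult
    metrics: MetricsReport
    wall_seconds: float

    @property
    def subject_accuracy(self) -> float:
        return self.metrics.subject_metrics["accuracy"]

    @property
    def trial_accuracy(self) -> float:
        return self.metrics.trial_metrics["accuracy"]

    @property
    def subject_kappa(self) -> float:
        return self.metrics.subject_kappa

    def predictions_frame(self):
        """Per-trial predictions as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for f in self.result.folds:
            for j, p in enumerate(f.trial_pred):
                rows.append({
                    "subject_id": f.held_out_subject,
                    "trial": j,
                    "true_label": f.true_label,
                    "predicted": p,
                    **{f"score_{c}": float(f.trial_scores[j, k])
                       for k, c in enumerate(self.result.classes)},
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        exp = self.experiment
        net = build_model(exp.architecture, seed=0, model_config=exp.model_config)
        lines = [
            "Leave-one-subject-out evaluation",
            "=" * 44,
            f"architecture:        {exp.architecture}",
            f"trainable params:    {count_parameters(net):,}",
            f"subjects (folds):    {len(self.result.folds)}",
            f"trials:              {exp.dataset.n_trials}",
            f"train seed:          {self.result.train_config.seed}",
            f"wall time:           {self.wall_seconds:.1f} s",
            "",
            self.metrics.summary(),
        ]
        return "\n".join(lines)

    def plot_confusion(self, level: str = "subject", ax=None):
        """Heatmap of the confusion matrix at ``level`` ("subject"/"trial")."""
        import matplotlib.pyplot as plt

        conf = (self.metrics.subject_confusion if level == "subject"
                else self.metrics.trial_confusion)
        if ax is None:
            _, ax = plt.subplots(figsize=(3.5, 3))
        im = ax.imshow(conf, cmap="Blues")
        classes = self.metrics.classes
        ax.set_xticks(range(len(classes)), classes)
        ax.set_yticks(range(len(classes)), classes)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(f"{level}-level confusion")
        for i in range(conf.shape[0]):
            for j in range(conf.shape[1]):
                ax.text(j, i, str(conf[i, j]), ha="center", va="center",
                        color="black" if conf[i, j] < conf.max() / 2 else "white")
        ax.figure.colorbar(im, ax=ax, shrink=0.8)
        return ax

    def save(self, out_dir) -> None:
        """Write metrics JSON, per-trial CSV and confusion CSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(json.dumps(self.metrics.to_dict(), indent=2))
        self.predictions_frame().to_csv(out / "trial_predictions.csv", index=False)
        np.savetxt(out / "confusion_trial.csv", self.metrics.trial_confusion,
                   fmt="%d", delimiter=",",
                   header=",".join(self.metrics.classes), comments="")
        np.savetxt(out / "confusion_subject.csv", self.metrics.subject_confusion,
                   fmt="%d", delimiter=",",
                   header=",".join(self.metrics.classes), comments="")


@dataclass
class SeedRobustness:
    """Subject-level accuracy across repeated seeded LOSO runs."""

    seeds: tuple[int, ...]
    runs: list[LOSOResults]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([100.0 * r.subject_accuracy for r in self.runs])

    def summary(self) -> str:
        acc = self.accuracies
        per_seed = ", ".join(f"{s}: {a:.2f}%" for s, a in zip(self.seeds, acc))
        return (f"subject-level accuracy over seeds {{{per_seed}}} -> "
                f"{acc.mean():.2f} +/- {acc.std(ddof=1) if len(acc) > 1 else 0.0:.2f}%")


def shuffle_subject_labels(ts: TrialSet, rng: np.random.Generator) -> TrialSet:
    """Chance-level control: permute class labels across subjects (the
    subject-to-label assignment is shuffled; trials keep their subject)."""
    subjects = ts.subjects()
    labels = [ts.subject_label(s) for s in subjects]
    perm = rng.permutation(len(subjects))
    remap = {s: labels[perm[i]] for i, s in enumerate(subjects)}
    new_labels = np.array([remap[str(s)] for s in ts.subject_ids])
    return TrialSet(ts.trials.copy(), ts.subject_ids.copy(), new_labels,
                    ts.sampling_rate_hz, list(ts.channel_names))
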