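"""Leave-one-person-out evaluation, intervals, confusion matrices and sweeps.

Every subject serves once as the held-out test set while the remaining
subjects train the classifier, so reported accuracy measures generalization
to unseen people rather than to unseen windows of known people. One training
subject is additionally held out per fold for early stopping. Augmented
copies of training samples never enter validation or test folds; this is
enforced by construction and asserted on sample provenance.

The summary statistic is mean fold accuracy with a 95% normal-approximation
half-width, 1.96 * SD(fold accuracies) / sqrt(n_folds); the unit of
evaluation is the window sample, and confusion matrices are row-normalized
over ground-truth classes.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentPolicy, augment_dataset
from .models import ModelConfig, build_model, predict, train

__all__ = [
    "SequenceSample",
    "FoldPlan",
    "EvalReport",
    "lopo_folds",
    "accuracy_interval",
    "confusion_matrix",
    "run_lopo",
    "subject_sweep",
]


@dataclass(frozen=True, eq=False)
class SequenceSample:
    """A raw-signal classifier input (frames x features) with provenance;
    structurally interchangeable with a heatmap sample."""

    tensor: np.ndarray
    label: str
    subject_id: str
    start_frame: int = 0
    augmented: bool = False


@dataclass(frozen=True)
class FoldPlan:
    """One fold per subject; test subjects partition the roster."""

    subjects: tuple[str, ...]
    folds: tuple[tuple[str, tuple[str, ...]], ...]  # (test_subject, train_subjects)


@dataclass
class EvalReport:
    fold_subjects: list[str]
    per_fold_accuracy: list[float]
    mean_accuracy: float
    interval_halfwidth: float | None
    confusion: np.ndarray  # C x C row-normalized
    confusion_counts: np.ndarray  # C x C raw counts
    labels: list[str]
    seed: int
    config_hash: str

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {
            "interval": "mean +/- 1.96*SD(folds)/sqrt(n_folds); unit = window sample",
            "fold_subjects": self.fold_subjects,
            "per_fold_accuracy": self.per_fold_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "interval_halfwidth": self.interval_halfwidth,
            "labels": self.labels,
            "seed": self.seed,
            "config_hash": self.config_hash,
        }
        (out_dir / "report.json").write_text(json.dumps(payload, indent=2))
        pd.DataFrame(self.confusion, index=self.labels, columns=self.labels).to_csv(
            out_dir / "confusion.csv"
        )


def lopo_folds(subject_ids) -> FoldPlan:
    """Deterministic leave-one-person-out plan over sorted unique subjects."""
    roster = tuple(sorted(set(subject_ids)))
    if len(roster) < 2:
        raise ValueError("leave-one-person-out needs at least 2 subjects")
    folds = tuple(
        (test, tuple(s for s in roster if s != test)) for test in roster
    )
    return FoldPlan(subjects=roster, folds=folds)


def accuracy_interval(per_fold_accuracy) -> tuple[float, float | None]:
    """Mean fold accuracy and 95% normal-approximation half-width; the
    half-width is undefined (None) with fewer than 2 folds."""
    acc = np.asarray(per_fold_accuracy, float)
    mean = float(acc.mean())
    if acc.size < 2:
        return mean, None
    half = 1.96 * float(acc.std(ddof=1)) / np.sqrt(acc.size)
    return mean, half


def confusion_matrix(y_true, y_pred, n_classes: int, normalize: bool = True) -> np.ndarray:
    """Row-normalized confusion matrix; entry (i, j) is the fraction of
    true-class-i samples predicted as j. Rows without samples stay zero."""
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= n_classes or y_pred.min() < 0 or y_pred.max() >= n_classes
    ):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes))
    np.add.at(counts, (y_true, y_pred), 1.0)
    if not normalize:
        return counts
    row = counts.sum(axis=1, keepdims=True)
    out = np.divide(counts, row, out=np.zeros_like(counts), where=row > 0)
    return out


def _config_hash(cfg: ModelConfig, extra: dict) -> str:
    payload = json.dumps({"cfg": asdict(cfg), **extra}, sort_keys=True, default=str)
    return hashlib.md5(payload.encode()).hexdigest()[:12]


def run_lopo(
    samples: list,
    kind: str,
    labels: list[str] | None = None,
    augment_policy: AugmentPolicy | None = None,
    seed: int = 0,
    **config_overrides,
) -> EvalReport:
    """Train and evaluate one model kind under leave-one-person-out CV.

    ``samples`` carry tensor/label/subject_id/augmented provenance (heatmap
    samples for the image model, sequence samples for the raw models). Per
    fold, one training subject is held out (seeded choice) for early
    stopping; the augmentation policy, if any, is applied to the training
    split only.
    """
    if any(s.augmented for s in samples):
        raise ValueError("input samples must be originals; augmentation happens per fold")
    labels = labels or sorted({s.label for s in samples})
    lab_idx = {l: k for k, l in enumerate(labels)}
    plan = lopo_folds([s.subject_id for s in samples])
    input_shape = samples[0].tensor.shape
    cfg = ModelConfig(kind=kind, n_classes=len(labels), input_shape=input_shape,
                      seed=seed, **config_overrides)

    fold_acc: list[float] = []
    y_true_all: list[int] = []
    y_pred_all: list[int] = []
    for k_fold, (test_subject, train_subjects) in enumerate(plan.folds):
        rng = np.random.default_rng([seed, k_fold])
        test = [s for s in samples if s.subject_id == test_subject]
        if len(train_subjects) > 1:
            val_subject = train_subjects[rng.integers(len(train_subjects))]
            val = [s for s in samples if s.subject_id == val_subject]
            tr = [s for s in samples if s.subject_id not in (test_subject, val_subject)]
        else:
            # two-subject cohort: early-stopping validation comes from a
            # within-subject split of the single training subject
            pool = [s for s in samples if s.subject_id == train_subjects[0]]
            order = rng.permutation(len(pool))
            n_val = max(1, len(pool) // 5)
            val = [pool[i] for i in order[:n_val]]
            tr = [pool[i] for i in order[n_val:]]
        if augment_policy is not None:
            tr = augment_dataset(tr, augment_policy)
        # provenance guard: nothing augmented may sit in val/test
        assert not any(s.augmented for s in test + val)
        assert all(s.subject_id != test_subject for s in tr)

        Xtr = np.stack([s.tensor for s in tr])
        ytr = np.array([lab_idx[s.label] for s in tr])
        Xva = np.stack([s.tensor for s in val])
        yva = np.array([lab_idx[s.label] for s in val])
        Xte = np.stack([s.tensor for s in test])
        yte = np.array([lab_idx[s.label] for s in test])

        model = build_model(
            ModelConfig(**{**asdict(cfg), "seed": seed + 1000 * k_fold})
        )
        train(model, Xtr, ytr, Xva, yva)
        preds = np.array([p.predicted for p in predict(model, Xte, batch=cfg.batch_size)])
        fold_acc.append(float(np.mean(preds == yte)))
        y_true_all.extend(yte.tolist())
        y_pred_all.extend(preds.tolist())

    mean, half = accuracy_interval(fold_acc)
    return EvalReport(
        fold_subjects=list(plan.subjects),
        per_fold_accuracy=fold_acc,
        mean_accuracy=mean,
        interval_halfwidth=half,
        confusion=confusion_matrix(y_true_all, y_pred_all, len(labels)),
        confusion_counts=confusion_matrix(y_true_all, y_pred_all, len(labels), normalize=False),
        labels=list(labels),
        seed=seed,
        config_hash=_config_hash(cfg, {"augment": augment_policy is not None}),
    )


def subject_sweep(
    samples_by_model: dict[str, list],
    subject_counts,
    n_repeats: int = 3,
    seed: int = 0,
    **config_overrides,
) -> pd.DataFrame:
    """Accuracy versus cohort size: for each subject count n, repeat LOPO on
    seeded random subject subsets (drawn without replacement) and tabulate
    mean accuracy with its half-width per model kind. n equal to the full
    roster collapses to a single subset (plain LOPO)."""
    rows = []
    for kind, samples in samples_by_model.items():
        roster = sorted({s.subject_id for s in samples})
        for n in subject_counts:
            if n < 2:
                warnings.warn(f"skipping subject count {n} < 2")
                continue
            if n > len(roster):
                raise ValueError(f"subject count {n} exceeds cohort size {len(roster)}")
            reps = 1 if n == len(roster) else n_repeats
            for r in range(reps):
                rng = np.random.default_rng([seed, n, r])
                subset = set(rng.choice(roster, size=n, replace=False))
                sub_samples = [s for s in samples if s.subject_id in subset]
                report = run_lopo(sub_samples, kind, seed=seed, **config_overrides)
                rows.append(
                    {
                        "model": kind,
                        "n_subjects": n,
                        "repeat": r,
                        "mean_accuracy": report.mean_accuracy,
                        "interval_halfwidth": report.interval_halfwidth,
                    }
                )
    return pd.DataFrame(rows)
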