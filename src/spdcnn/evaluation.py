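"""Accuracy evaluation across folds and the subject-distance analysis.

Besides per-user accuracy and fold aggregation this module implements the
descriptor-shift diagnostic: per class, all subjects' samples are pooled,
projected to 2-D by PCA, and the mean Euclidean distance over all
inter-subject sample pairs is computed — once on raw flattened trials and
once on SPD descriptors.  A smaller distance for the descriptors means the
representation closes the gap between subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .descriptor import describe_dataset
from .exceptions import DataError
from .network import ModelParams, forward_batch
from .sampler import Fold, sample_task
from .synthetic import EEGDataset
from .training import (
    MetaResult,
    TrainingConfig,
    domain_adapt,
    group_by_subject,
    meta_update,
    pretrain,
)

__all__ = [
    "EvalReport",
    "DistanceReport",
    "evaluate_user",
    "aggregate_folds",
    "subject_distance",
    "run_fold",
    "run_study",
]


@dataclass
class FoldAggregate:
    mean: float
    std: float
    n_folds: int

    @property
    def degenerate(self) -> bool:
        """True when only one fold contributed and the std is not estimable."""
        return self.n_folds < 2


@dataclass
class EvalReport:
    """Per-(fold, strategy, shots, subject) accuracies plus aggregates."""

    records: pd.DataFrame
    config_seed: int = 0

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- sample std over folds for each (strategy, shots)."""
        per_fold = (
            self.records.groupby(["strategy", "shots", "fold"])["accuracy"].mean().reset_index()
        )
        rows = []
        for (strategy, shots), grp in per_fold.groupby(["strategy", "shots"]):
            agg = aggregate_folds(grp["accuracy"].tolist())
            rows.append(
                {
                    "strategy": strategy,
                    "shots": shots,
                    "mean": agg.mean,
                    "std": agg.std,
                    "n_folds": agg.n_folds,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class DistanceReport:
    """Averaged inter-subject 2-D distances and the projections behind them."""

    representation: str
    distances: dict[int, float] = field(default_factory=dict)
    projections: dict[int, pd.DataFrame] = field(default_factory=dict)

    @property
    def mean_distance(self) -> float:
        return float(np.mean(list(self.distances.values())))


def evaluate_user(params: ModelParams, query) -> float:
    """Fraction of correctly predicted query descriptors for one user."""
    query = list(query)
    if not query:
        raise DataError("query set is empty")
    mats = np.stack([s.matrix for s in query])
    labels = np.asarray([s.label for s in query])
    preds = forward_batch(params, mats).argmax(axis=1)
    return float(np.mean(preds == labels))


def aggregate_folds(fold_accuracies) -> FoldAggregate:
    """Mean and sample (ddof=1) standard deviation over fold accuracies."""
    vals = np.asarray(list(fold_accuracies), dtype=float)
    if vals.size == 0:
        raise DataError("no fold accuracies to aggregate")
    std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return FoldAggregate(mean=float(vals.mean()), std=std, n_folds=int(vals.size))


# ---------------------------------------------------------------------------
# subject-distance analysis


def _flatten_samples(samples) -> np.ndarray:
    rows = []
    for s in samples:
        arr = s.matrix if hasattr(s, "matrix") else s.data
        rows.append(np.asarray(arr, dtype=float).ravel())
    return np.stack(rows)


def subject_distance(
    samples_by_subject: dict,
    representation: str = "spd",
    centroids: bool = False,
) -> DistanceReport:
    """Averaged inter-subject Euclidean distance in a per-class 2-D PCA space.

    For each class, every subject's samples (flattened to vectors) are
    pooled, mean-centered, and projected onto the first two principal
    components; the reported distance is the mean over all pairs of
    projected samples belonging to different subjects (or over subject
    centroids with ``centroids=True``).
    """
    subjects = sorted(samples_by_subject)
    if len(subjects) < 2:
        raise DataError("subject-distance analysis needs at least two subjects")
    classes = sorted(
        {s.label for subj in subjects for s in samples_by_subject[subj]}
    )
    report = DistanceReport(representation=representation)
    for cls in classes:
        per_subject = {}
        for subj in subjects:
            sel = [s for s in samples_by_subject[subj] if s.label == cls]
            if not sel:
                warnings.warn(
                    f"subject {subj!r} has no samples of class {cls}; excluded", stacklevel=2
                )
                continue
            per_subject[subj] = _flatten_samples(sel)
        if len(per_subject) < 2:
            raise DataError(f"fewer than two subjects have samples of class {cls}")
        pooled = np.vstack(list(per_subject.values()))
        pca = PCA(n_components=2, svd_solver="full")
        pca.fit(pooled - pooled.mean(axis=0))
        proj = {
            subj: pca.transform(x - pooled.mean(axis=0)) for subj, x in per_subject.items()
        }
        if centroids:
            cents = {subj: p.mean(axis=0) for subj, p in proj.items()}
            dists = [
                np.linalg.norm(cents[a] - cents[b])
                for i, a in enumerate(per_subject)
                for b in list(per_subject)[i + 1 :]
            ]
            report.distances[cls] = float(np.mean(dists))
        else:
            subj_list = list(per_subject)
            total, count = 0.0, 0
            for i, a in enumerate(subj_list):
                for b in subj_list[i + 1 :]:
                    pa, pb = proj[a], proj[b]
                    diff = pa[:, None, :] - pb[None, :, :]
                    d = np.sqrt((diff**2).sum(axis=2))
                    total += d.sum()
                    count += d.size
            report.distances[cls] = total / count
        frames = []
        for subj, p in proj.items():
            frames.append(pd.DataFrame({"subject": subj, "pc1": p[:, 0], "pc2": p[:, 1]}))
        report.projections[cls] = pd.concat(frames, ignore_index=True)
    return report


# ---------------------------------------------------------------------------
# ML / TL / MTL comparison harness


def run_fold(
    dataset: EEGDataset,
    fold: Fold,
    config: TrainingConfig,
    strategies=("ml", "tl", "mtl"),
    shots=(10,),
    norm_scope: str = "train",
) -> pd.DataFrame:
    """One fold end to end: descriptors, pre-train, (meta), per-user adaptation.

    Strategies: ``ml`` — pre-train only, zero-shot on test users; ``tl`` —
    pre-train + classifier fine-tuning on the user's support; ``mtl`` —
    pre-train + SS meta-update + fine-tuning.  For every test user one
    episodic task is drawn; all strategies score on the same query set.
    Returns tidy records (strategy, shots, fold, subject, accuracy).
    """
    fit_on = None if norm_scope == "all" else fold.train_subjects
    samples, _stats = describe_dataset(dataset, fit_on=fit_on)
    by_subject = group_by_subject(samples)
    train = [s for subj in fold.train_subjects for s in by_subject[subj]]
    val = [s for subj in fold.val_subjects for s in by_subject[subj]]

    pre = pretrain(train, config, n_classes=dataset.n_classes)
    meta: MetaResult | None = None
    if "mtl" in strategies:
        meta = meta_update(pre.params, train, val, config)

    max_shot = max([s for s in shots if s > 0], default=config.k_shot)
    records = []
    for u, subject in enumerate(fold.test_subjects):
        task = sample_task(
            by_subject[subject],
            n_way=dataset.n_classes,
            k_shot=max_shot,
            n_query=config.n_query,
            seed=np.random.default_rng(
                np.random.SeedSequence([config.seed, 6, fold.fold_index, u])
            ),
            subject=subject,
        )
        for shot in shots:
            support = (
                [s for k, s in enumerate(task.support) if k % max_shot < shot]
                if 0 < shot < max_shot
                else task.support
            )
            for strategy in strategies:
                if strategy != "ml" and shot == 0:
                    continue  # fine-tuning strategies need a support set
                if strategy == "ml":
                    model, used_shot = pre.params, 0
                elif strategy == "tl":
                    # fine-tune the pre-trained classifier block
                    model = domain_adapt(
                        pre.params, support, config, theta_init=pre.params.classifier
                    )
                    used_shot = shot
                elif strategy == "mtl":
                    assert meta is not None
                    # adapt from the deployment classifier carried by the meta model
                    model = domain_adapt(
                        meta.params, support, config, theta_init=meta.params.classifier
                    )
                    used_shot = shot
                else:
                    raise DataError(f"unknown strategy {strategy!r}")
                acc = evaluate_user(model, task.query)
                records.append(
                    {
                        "strategy": strategy,
                        "shots": used_shot,
                        "fold": fold.fold_index,
                        "subject": subject,
                        "accuracy": acc,
                    }
                )
    frame = pd.DataFrame(records)
    # zero-shot ml is shot-independent; drop duplicates from the shots loop
    return frame.drop_duplicates(subset=["strategy", "shots", "fold", "subject"]).reset_index(
        drop=True
    )


def run_study(
    dataset: EEGDataset,
    folds,
    config: TrainingConfig,
    strategies=("ml", "tl", "mtl"),
    shots=(10,),
    norm_scope: str = "train",
) -> EvalReport:
    """Run several folds and collect a tidy accuracy report."""
    frames = [
        run_fold(dataset, fold, config, strategies=strategies, shots=shots, norm_scope=norm_scope)
        for fold in folds
    ]
    return EvalReport(records=pd.concat(frames, ignore_index=True), config_seed=config.seed)
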