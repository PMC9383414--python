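"""Cross-subject folds and N-way K-shot episodic task sampling.

A fold partitions the subject pool into disjoint train / validation / test
roles; accuracy is later aggregated over many random folds.  An episodic
task draws class-balanced, disjoint support and query sets from a single
subject, so each task is one subject-specific few-shot classification
problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, SamplingError

__all__ = ["Fold", "EpisodicTask", "make_folds", "sample_task", "build_meta_batches", "sample_tasks_evenly"]


@dataclass(frozen=True)
class Fold:
    """Disjoint train/validation/test subject partition."""

    train_subjects: tuple
    val_subjects: tuple
    test_subjects: tuple
    fold_index: int = 0

    def __post_init__(self) -> None:
        groups = [set(self.train_subjects), set(self.val_subjects), set(self.test_subjects)]
        total = sum(len(g) for g in groups)
        if len(groups[0] | groups[1] | groups[2]) != total:
            raise ConfigurationError("fold subject groups must be pairwise disjoint")


@dataclass
class EpisodicTask:
    """One subject-specific N-way K-shot task with support and query sets."""

    subject: str
    support: list
    query: list
    task_id: int = 0
    classes: tuple = field(default_factory=tuple)


def make_folds(
    subjects,
    n_val: int = 3,
    n_test: int = 2,
    n_folds: int = 18,
    seed: int = 0,
    balanced: bool = False,
) -> list[Fold]:
    """Draw ``n_folds`` random subject partitions.

    Within each fold, validation and test subjects are drawn without
    replacement and the remainder trains.  Folds are kept distinct as
    (validation, test) pairs while enough combinations exist; beyond that a
    warning is emitted and repetition is allowed.  With ``balanced=True``
    the test users cycle round-robin over the subject pool instead of being
    fully random.
    """
    subjects = list(subjects)
    n = len(subjects)
    if n_val < 0 or n_test < 1 or n_folds < 1:
        raise ConfigurationError("need n_val >= 0, n_test >= 1, n_folds >= 1")
    if n_val + n_test >= n:
        raise ConfigurationError(
            f"cannot reserve {n_val} validation + {n_test} test subjects out of {n}"
        )
    rng = np.random.default_rng(seed)
    # number of distinct (val, test) set pairs
    from math import comb

    n_distinct = comb(n, n_val) * comb(n - n_val, n_test)
    if n_folds > n_distinct:
        warnings.warn(
            f"{n_folds} folds requested but only {n_distinct} distinct partitions exist; "
            "allowing repetition",
            stacklevel=2,
        )
    folds: list[Fold] = []
    seen: set = set()
    order = list(subjects)
    for i in range(n_folds):
        for _attempt in range(1000):
            if balanced:
                # round-robin test users, random validation among the rest
                start = (i * n_test) % n
                test = [order[(start + j) % n] for j in range(n_test)]
                rest = [s for s in subjects if s not in test]
                val = list(rng.choice(rest, size=n_val, replace=False))
            else:
                perm = list(rng.permutation(subjects))
                val, test = perm[:n_val], perm[n_val : n_val + n_test]
            key = (frozenset(val), frozenset(test))
            if key not in seen or len(seen) >= n_distinct:
                break
        seen.add(key)
        train = tuple(s for s in subjects if s not in set(val) | set(test))
        folds.append(
            Fold(
                train_subjects=train,
                val_subjects=tuple(val),
                test_subjects=tuple(test),
                fold_index=i,
            )
        )
    return folds


def _samples_by_class(samples, subject: str):
    by_class: dict[int, list] = {}
    for s in samples:
        if s.subject != subject:
            raise SamplingError(
                f"sample of subject {s.subject!r} passed to a task for {subject!r}"
            )
        by_class.setdefault(s.label, []).append(s)
    return by_class


def sample_task(
    samples,
    n_way: int,
    k_shot: int,
    n_query: int,
    seed=0,
    subject: str | None = None,
    task_id: int = 0,
) -> EpisodicTask:
    """Draw one N-way K-shot task from a single subject's samples.

    ``samples`` may be EEG trials or SPD descriptors — anything with
    ``label`` and ``subject`` attributes.  Support and query are disjoint
    and exactly class-balanced.  Deterministic given ``seed`` (an int or a
    Generator).
    """
    samples = list(samples)
    if not samples:
        raise SamplingError("no samples to draw a task from")
    if subject is None:
        subject = samples[0].subject
    by_class = _samples_by_class(samples, subject)
    classes = sorted(by_class)
    if n_way > len(classes):
        raise SamplingError(
            f"subject {subject!r} has {len(classes)} classes, cannot sample {n_way}-way"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = sorted(rng.choice(classes, size=n_way, replace=False).tolist())
    support, query = [], []
    need = k_shot + n_query
    for cls in chosen:
        pool = by_class[cls]
        if len(pool) < need:
            raise SamplingError(
                f"subject {subject!r}, class {cls}: {len(pool)} samples available, "
                f"need {need} (k_shot={k_shot} + n_query={n_query})"
            )
        idx = rng.choice(len(pool), size=need, replace=False)
        support.extend(pool[i] for i in idx[:k_shot])
        query.extend(pool[i] for i in idx[k_shot:])
    return EpisodicTask(
        subject=subject, support=support, query=query, task_id=task_id, classes=tuple(chosen)
    )


def sample_tasks_evenly(
    samples_by_subject: dict,
    subjects,
    n_tasks: int,
    n_way: int,
    k_shot: int,
    n_query: int,
    rng,
) -> list[EpisodicTask]:
    """``n_tasks`` tasks cycling through ``subjects`` so each contributes evenly."""
    subjects = list(subjects)
    if not subjects:
        raise SamplingError("no subjects to sample tasks from")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    tasks = []
    for t in range(n_tasks):
        subj = subjects[t % len(subjects)]
        tasks.append(
            sample_task(
                samples_by_subject[subj],
                n_way=n_way,
                k_shot=k_shot,
                n_query=n_query,
                seed=rng,
                subject=subj,
                task_id=t,
            )
        )
    return tasks


def build_meta_batches(tasks, batch_size: int, allow_partial: bool = False) -> list[list]:
    """Partition tasks in order into meta-batches of ``batch_size``."""
    if batch_size <= 0:
        raise ConfigurationError(f"batch_size must be positive, got {batch_size}")
    tasks = list(tasks)
    if len(tasks) % batch_size != 0 and not allow_partial:
        raise ConfigurationError(
            f"{len(tasks)} tasks do not divide into meta-batches of {batch_size} "
            "(pass allow_partial=True to keep the remainder)"
        )
    return [tasks[i : i + batch_size] for i in range(0, len(tasks), batch_size)]
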