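"""Spatial-covariance (SPD) descriptors and their dataset-level normalization.

A zero-mean d-channel trial ``X`` (d x T) is summarized by its spatial
covariance ``C = (1/T) X X^T``, a d x d symmetric positive-semidefinite
matrix that captures per-channel power and inter-channel coupling while
discarding trial length.  Descriptors are then standardized elementwise
against the statistics of a reference sample set,
``C* = (C - C_mean) / C_std``, which stabilizes the downstream network's
input scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import (
    DataError,
    DegenerateTrialError,
    DimensionError,
    StateError,
)
from .synthetic import EEGDataset, EEGTrial

__all__ = [
    "SPDSample",
    "NormalizerStats",
    "center_trial",
    "compute_covariance",
    "fit_normalizer",
    "apply_normalizer",
    "describe_dataset",
]

SYMMETRY_ATOL = 1e-9
PSD_EIGEN_TOL = -1e-9


@dataclass
class SPDSample:
    """A d x d covariance descriptor with its label and subject."""

    matrix: np.ndarray
    label: int
    subject: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise DimensionError("descriptor matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=SYMMETRY_ATOL):
            raise DataError("descriptor matrix must be symmetric")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


@dataclass
class NormalizerStats:
    """Elementwise mean/std over a fitted descriptor set.

    ``std`` entries below ``epsilon`` are replaced by 1 so constant entries
    map to exactly zero instead of dividing by ~0.
    """

    mean: np.ndarray
    std: np.ndarray
    n_fitted: int
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != self.std.shape:
            raise DimensionError("mean and std shapes differ")
        if np.any(self.std < 0):
            raise DataError("std entries must be nonnegative")
        if self.n_fitted < 1:
            raise DataError("n_fitted must be >= 1")


def center_trial(trial: EEGTrial) -> EEGTrial:
    """Subtract each channel's own mean; idempotent."""
    if trial.n_samples < 2:
        raise DegenerateTrialError(
            f"trial needs T >= 2 samples to be centered, got {trial.n_samples}"
        )
    centered = trial.data - trial.data.mean(axis=1, keepdims=True)
    return EEGTrial(data=centered, label=trial.label, subject=trial.subject)


def compute_covariance(trial: EEGTrial, center: bool = True) -> SPDSample:
    """The spatial covariance descriptor ``C = (1/T) X X^T``.

    Channels are mean-centered first by default, since the covariance
    interpretation requires zero-mean rows; pass ``center=False`` if the
    trial is already centered upstream.
    """
    if not np.all(np.isfinite(trial.data)):
        raise DataError("trial contains non-finite values")
    x = center_trial(trial).data if center else trial.data
    t = x.shape[1]
    c = (x @ x.T) / t
    c = 0.5 * (c + c.T)  # kill asymmetric rounding residue
    return SPDSample(matrix=c, label=trial.label, subject=trial.subject, normalized=False)


def fit_normalizer(samples, epsilon: float = 1e-8) -> NormalizerStats:
    """Elementwise mean and population (1/n) standard deviation of a set.

    Entries whose std falls below ``epsilon`` are guarded to 1.
    """
    samples = list(samples)
    if not samples:
        raise DataError("cannot fit normalizer on an empty collection")
    dims = {s.dim for s in samples}
    if len(dims) != 1:
        raise DimensionError(f"mixed descriptor dimensions: {sorted(dims)}")
    for s in samples:
        if s.normalized:
            raise StateError("normalizer must be fitted on unnormalized descriptors")
    stack = np.stack([s.matrix for s in samples])
    mean = stack.mean(axis=0)
    std = stack.std(axis=0)  # population (ddof=0)
    std = np.where(std < epsilon, 1.0, std)
    # mean/std of symmetric matrices are symmetric; enforce exactly
    mean = 0.5 * (mean + mean.T)
    std = 0.5 * (std + std.T)
    return NormalizerStats(mean=mean, std=std, n_fitted=len(samples), epsilon=epsilon)


def apply_normalizer(sample: SPDSample, stats: NormalizerStats) -> SPDSample:
    """Standardize one descriptor: ``C* = (C - C_mean) / C_std`` elementwise."""
    if sample.normalized:
        raise StateError("descriptor is already normalized")
    if sample.matrix.shape != stats.mean.shape:
        raise DimensionError(
            f"descriptor is {sample.matrix.shape}, stats are {stats.mean.shape}"
        )
    out = (sample.matrix - stats.mean) / stats.std
    return replace(sample, matrix=out, normalized=True)


def describe_dataset(
    dataset: EEGDataset,
    stats: NormalizerStats | None = None,
    fit_on=None,
    epsilon: float = 1e-8,
) -> tuple[list[SPDSample], NormalizerStats]:
    """Covariance + normalization for every trial of a dataset.

    By default the normalizer is fitted on the descriptors of the subjects
    in ``fit_on`` (all subjects when None) and applied to everything.  In a
    cross-subject protocol pass the *training* subjects as ``fit_on`` so no
    statistic leaks from validation/test users; fitting on all subjects
    reproduces the single-pool reading instead.  A pre-fitted ``stats``
    bypasses fitting entirely.
    """
    raw = [compute_covariance(t) for t in dataset.trials]
    if stats is None:
        if fit_on is None:
            fit_samples = raw
        else:
            wanted = set([fit_on] if isinstance(fit_on, str) else fit_on)
            fit_samples = [s for s in raw if s.subject in wanted]
        stats = fit_normalizer(fit_samples, epsilon=epsilon)
    return [apply_normalizer(s, stats) for s in raw], stats
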