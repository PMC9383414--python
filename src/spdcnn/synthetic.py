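"""Synthetic multi-subject EEG-like trial generator.

Classes are encoded purely in the spatial covariance of zero-mean
multichannel trials; subject identity perturbs the forward model through a
linear mixing matrix ``A_s = I + eps * R_s``, producing a controllable
cross-subject domain shift.  This stands in for multi-subject motor-imagery
recordings whose class information lives in the second-order statistics.

The generator deliberately does *not* model temporal EEG structure
(1/f spectra, event-related desynchronization): the downstream descriptor
only looks at spatial covariance, so class information is placed exactly
there and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DataError

__all__ = [
    "SubjectSpec",
    "ClassSpec",
    "EEGTrial",
    "EEGDataset",
    "mixing_matrix",
    "expected_covariance",
    "make_class_specs",
    "generate_subject_dataset",
    "generate_study",
    "quadratic_oracle_predict",
]

#: Default synthetic geometry: the smallest comfortable channel count that
#: survives the network's five valid 2x2 convolutions and one 2x2 pool
#: (minimum feasible is 9), four motor-imagery-like classes, one-second
#: trials at 256 Hz.
DEFAULT_CHANNELS = 12
DEFAULT_CLASSES = 4
DEFAULT_SAMPLES = 256
DEFAULT_NOISE_SD = 1.0
DEFAULT_SEPARATION = 1.0
DEFAULT_BACKGROUND_SCALE = 6.0
DEFAULT_TRIALS_PER_CLASS = 60


@dataclass(frozen=True)
class SubjectSpec:
    """One simulated subject.

    Parameters
    ----------
    subject_id : str
        Opaque identifier.
    mixing_strength : float
        Magnitude ``eps >= 0`` of the subject-specific mixing perturbation.
        ``eps = 0`` means every subject shares the identical forward model.
    seed : int
        Seed for the subject's fixed random mixing matrix ``R_s``.
    """

    subject_id: str
    mixing_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mixing_strength < 0:
            raise ConfigurationError(
                f"mixing_strength must be >= 0, got {self.mixing_strength}"
            )


@dataclass(frozen=True)
class ClassSpec:
    """One class, defined by its d x d source covariance ``Sigma_k``."""

    class_id: int
    source_covariance: np.ndarray

    def __post_init__(self) -> None:
        sigma = np.asarray(self.source_covariance, dtype=float)
        if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
            raise ConfigurationError("source_covariance must be square")
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise ConfigurationError("source_covariance must be symmetric")
        if np.linalg.eigvalsh(sigma).min() <= 0:
            raise ConfigurationError("source_covariance must be positive definite")
        object.__setattr__(self, "source_covariance", sigma)

    @property
    def n_channels(self) -> int:
        return self.source_covariance.shape[0]


@dataclass
class EEGTrial:
    """A single (channels x samples) trial with its label and subject."""

    data: np.ndarray
    label: int
    subject: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("trial data must be a 2-D (channels x samples) matrix")
        d, t = self.data.shape
        if d < 1 or t < 2:
            raise DataError(f"trial must have d >= 1 channels and T >= 2 samples, got {d}x{t}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("trial data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EEGDataset:
    """An ordered collection of trials sharing channel count and label space."""

    trials: list[EEGTrial]
    n_channels: int
    n_classes: int
    sampling_rate: float = 256.0
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for trial in self.trials:
            if trial.n_channels != self.n_channels:
                raise DataError(
                    f"trial of subject {trial.subject!r} has {trial.n_channels} channels, "
                    f"dataset declares {self.n_channels}"
                )
            if not 0 <= trial.label < self.n_classes:
                raise DataError(f"label {trial.label} outside 0..{self.n_classes - 1}")
        if not self.class_names:
            self.class_names = [f"class{k}" for k in range(self.n_classes)]

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def subjects(self) -> list[str]:
        """Subject ids in order of first appearance."""
        seen: dict[str, None] = {}
        for trial in self.trials:
            seen.setdefault(trial.subject, None)
        return list(seen)

    def restrict_to(self, subjects) -> "EEGDataset":
        """Sub-dataset containing only the given subjects."""
        wanted = set([subjects] if isinstance(subjects, str) else subjects)
        return EEGDataset(
            trials=[t for t in self.trials if t.subject in wanted],
            n_channels=self.n_channels,
            n_classes=self.n_classes,
            sampling_rate=self.sampling_rate,
            class_names=list(self.class_names),
        )

    def extend(self, other: "EEGDataset") -> None:
        if other.n_channels != self.n_channels or other.n_classes != self.n_classes:
            raise DataError("cannot merge datasets with different geometry")
        self.trials.extend(other.trials)


def mixing_matrix(subject: SubjectSpec, d: int) -> np.ndarray:
    """The subject's fixed forward model ``A_s = I + eps * R_s``.

    ``R_s`` has iid standard-normal entries scaled by ``1/d`` and is drawn
    once from the subject's own seed, so it is identical across calls and
    across classes.
    """
    rng = np.random.default_rng(subject.seed)
    r = rng.standard_normal((d, d)) / d
    return np.eye(d) + subject.mixing_strength * r


def expected_covariance(
    subject: SubjectSpec, cls: ClassSpec, noise_sd: float = 0.0
) -> np.ndarray:
    """Closed-form expected trial covariance ``A_s Sigma_k A_s^T + noise_sd^2 I``."""
    a = mixing_matrix(subject, cls.n_channels)
    return a @ cls.source_covariance @ a.T + noise_sd**2 * np.eye(cls.n_channels)


def make_class_specs(
    n_classes: int = DEFAULT_CLASSES,
    n_channels: int = DEFAULT_CHANNELS,
    separation: float = DEFAULT_SEPARATION,
    background_scale: float = DEFAULT_BACKGROUND_SCALE,
    seed: int = 0,
) -> list[ClassSpec]:
    """Well-separated SPD source covariances over a shared spatial background.

    All classes share one structured background ``B`` (random orthogonal
    eigenvectors, eigenvalues spread over [1, background_scale]) standing in
    for the large class-independent spatial structure of scalp recordings
    (volume conduction, common rhythms).  Each class then adds two rank-one
    "source pattern" bumps of magnitude ``separation``:
    ``Sigma_k = B + separation * (u_k u_k^T + v_k v_k^T)`` with ``u_k, v_k``
    class-specific random unit vectors.  Because the subject mixing acts on
    the full covariance, the dominant background makes subject identity a
    strong confound while class identity stays a comparatively small,
    consistent modulation — the regime that makes cross-subject transfer
    genuinely hard.
    """
    rng_bg = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    q, _ = np.linalg.qr(rng_bg.standard_normal((n_channels, n_channels)))
    lam = np.linspace(1.0, background_scale, n_channels)
    background = (q * lam) @ q.T
    background = 0.5 * (background + background.T)
    specs = []
    for k in range(n_classes):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        sigma = background.copy()
        for _ in range(2):
            u = rng.standard_normal(n_channels)
            u /= np.linalg.norm(u)
            sigma += separation * np.outer(u, u)
        specs.append(ClassSpec(class_id=k, source_covariance=sigma))
    return specs


def generate_subject_dataset(
    subject: SubjectSpec,
    classes: list[ClassSpec],
    n_trials_per_class: int = DEFAULT_TRIALS_PER_CLASS,
    n_samples: int = DEFAULT_SAMPLES,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    sampling_rate: float = 256.0,
) -> EEGDataset:
    """Generate one subject's trials, ``X = A_s Z + E``.

    ``Z`` has ``n_samples`` columns drawn from ``N(0, Sigma_k)`` and ``E``
    is iid Gaussian sensor noise with standard deviation ``noise_sd``.
    Expected trial covariance is ``A_s Sigma_k A_s^T + noise_sd^2 I``.
    Bit-deterministic given ``(subject.seed, seed)``.
    """
    if not classes:
        raise ConfigurationError("at least one ClassSpec required")
    d = classes[0].n_channels
    for cls in classes:
        if cls.n_channels != d:
            raise ConfigurationError(
                f"all ClassSpec must share channel count; got {cls.n_channels} and {d}"
            )
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd must be >= 0, got {noise_sd}")
    if n_trials_per_class < 0:
        raise ConfigurationError("n_trials_per_class must be >= 0")
    if n_samples < 2:
        raise ConfigurationError("n_samples must be >= 2")

    a = mixing_matrix(subject, d)
    rng = np.random.default_rng(seed)
    trials: list[EEGTrial] = []
    for cls in classes:
        chol = np.linalg.cholesky(cls.source_covariance)
        for _ in range(n_trials_per_class):
            z = chol @ rng.standard_normal((d, n_samples))
            x = a @ z
            if noise_sd > 0:
                x = x + noise_sd * rng.standard_normal((d, n_samples))
            trials.append(EEGTrial(data=x, label=cls.class_id, subject=subject.subject_id))
    return EEGDataset(
        trials=trials,
        n_channels=d,
        n_classes=len(classes),
        sampling_rate=sampling_rate,
    )


def generate_study(
    n_subjects: int,
    n_classes: int = DEFAULT_CLASSES,
    n_channels: int = DEFAULT_CHANNELS,
    n_trials_per_class: int = DEFAULT_TRIALS_PER_CLASS,
    n_samples: int = DEFAULT_SAMPLES,
    mixing_strength: float = 0.3,
    noise_sd: float = DEFAULT_NOISE_SD,
    separation: float = DEFAULT_SEPARATION,
    seed: int = 0,
) -> EEGDataset:
    """A full multi-subject study with a shared class structure.

    Every subject records ``n_trials_per_class`` trials per class through
    its own mixing matrix.  Subject mixing seeds and trial-noise seeds are
    derived from ``seed`` so the whole study is reproducible from one
    integer.
    """
    classes = make_class_specs(n_classes, n_channels, separation=separation, seed=seed)
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.generate_state(2 * n_subjects)
    dataset: EEGDataset | None = None
    for i in range(n_subjects):
        subject = SubjectSpec(
            subject_id=f"S{i + 1:02d}",
            mixing_strength=mixing_strength,
            seed=int(subject_seeds[2 * i] % (2**31)),
        )
        part = generate_subject_dataset(
            subject,
            classes,
            n_trials_per_class=n_trials_per_class,
            n_samples=n_samples,
            noise_sd=noise_sd,
            seed=int(subject_seeds[2 * i + 1] % (2**31)),
        )
        if dataset is None:
            dataset = part
        else:
            dataset.extend(part)
    assert dataset is not None
    return dataset


def quadratic_oracle_predict(trial: EEGTrial, covariances: list[np.ndarray]) -> int:
    """Bayes-optimal label under zero-mean Gaussian columns.

    Scores each candidate covariance by the Gaussian log-likelihood of the
    trial's columns and returns the argmax.  Used as an independent upper
    bound on achievable accuracy when the true per-subject covariances are
    known.
    """
    x = trial.data
    t = x.shape[1]
    best, best_ll = 0, -np.inf
    for k, sigma in enumerate(covariances):
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise DataError("oracle covariance must be positive definite")
        quad = np.sum(np.linalg.solve(sigma, x) * x)
        ll = -0.5 * (t * logdet + quad)
        if ll > best_ll:
            best, best_ll = k, ll
    return best
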