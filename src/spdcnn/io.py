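"""Portable artifact containers and run configuration.

Trials, descriptors, normalizer statistics and model parameters are stored
in HDF5 (hierarchical, language-neutral, diffable with h5dump); evaluation
results are plain delimited text.  Every artifact embeds the seed and the
hash of the configuration that produced it, and loaders refuse artifacts
whose geometry (d, K) does not match.

Raw EEG recordings in EDF/GDF can be ingested through ``mne`` (optional
dependency) given an event-to-class mapping and an epoch window.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .descriptor import NormalizerStats, SPDSample
from .exceptions import ConfigurationError, FormatError
from .network import (
    ClassifierParams,
    FeatureExtractorParams,
    ModelParams,
    N_CONV,
    SSParams,
)
from .synthetic import EEGDataset, EEGTrial
from .training import TrainingConfig

__all__ = [
    "TRIAL_FORMAT_VERSION",
    "save_dataset",
    "load_dataset",
    "save_descriptors",
    "load_descriptors",
    "save_model",
    "load_model",
    "RunConfig",
    "config_hash",
]

TRIAL_FORMAT_VERSION = "spdcnn-trials-1"
DESC_FORMAT_VERSION = "spdcnn-descriptors-1"
MODEL_FORMAT_VERSION = "spdcnn-model-1"

_STR = h5py.string_dtype(encoding="utf-8")


def config_hash(obj) -> str:
    """Stable content hash of a configuration mapping/dataclass."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_provenance(f: h5py.File, seed: int, cfg_hash: str) -> None:
    f.attrs["seed"] = int(seed)
    f.attrs["config_hash"] = cfg_hash


def _check_version(f: h5py.File, expected: str, path) -> None:
    version = f.attrs.get("format_version")
    if version != expected:
        raise FormatError(
            f"{path}: expected format {expected!r}, found {version!r}"
        )


# ---------------------------------------------------------------------------
# trial container


def save_dataset(path, dataset: EEGDataset, seed: int = 0, cfg_hash: str = "") -> None:
    """Write an :class:`EEGDataset` to the portable trial container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = TRIAL_FORMAT_VERSION
        f.attrs["n_channels"] = dataset.n_channels
        f.attrs["n_classes"] = dataset.n_classes
        f.attrs["sampling_rate"] = dataset.sampling_rate
        f.attrs["class_names"] = json.dumps(dataset.class_names)
        _write_provenance(f, seed, cfg_hash)
        if dataset.trials:
            data = np.stack([t.data for t in dataset.trials])
        else:
            data = np.zeros((0, dataset.n_channels, 2))
        f.create_dataset("trials", data=data, track_times=False)
        f.create_dataset(
            "labels",
            data=np.asarray([t.label for t in dataset.trials], dtype=np.int64),
            track_times=False,
        )
        f.create_dataset(
            "subjects",
            data=np.asarray([t.subject for t in dataset.trials], dtype=object),
            dtype=_STR,
            track_times=False,
        )


def _load_container(path) -> EEGDataset:
    with h5py.File(path, "r") as f:
        _check_version(f, TRIAL_FORMAT_VERSION, path)
        data = f["trials"][...]
        labels = f["labels"][...]
        subjects = [s.decode() if isinstance(s, bytes) else str(s) for s in f["subjects"][...]]
        trials = [
            EEGTrial(data=data[i], label=int(labels[i]), subject=subjects[i])
            for i in range(len(labels))
        ]
        return EEGDataset(
            trials=trials,
            n_channels=int(f.attrs["n_channels"]),
            n_classes=int(f.attrs["n_classes"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            class_names=json.loads(f.attrs["class_names"]),
        )


def _load_raw_eeg(path, fmt: str, event_map, tmin: float, tmax: float, subject: str):
    """Epoch an EDF/GDF recording into trials via mne (lazy import)."""
    if event_map is None:
        raise ConfigurationError(f"{fmt} ingestion requires an event-to-class mapping")
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise ConfigurationError(
            "reading raw EEG files requires the 'mne' package (install spdcnn[eeg])"
        ) from exc
    reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_gdf
    raw = reader(str(path), preload=True, verbose="error")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    wanted = {name: code for name, code in event_id.items() if name in event_map}
    if not wanted:
        import warnings

        warnings.warn(f"no events in {path} match the supplied mapping", stacklevel=3)
        return EEGDataset(
            trials=[],
            n_channels=raw.info["nchan"],
            n_classes=max(event_map.values(), default=0) + 1,
            sampling_rate=float(raw.info["sfreq"]),
        )
    epochs = mne.Epochs(
        raw,
        events,
        event_id=wanted,
        tmin=tmin,
        tmax=tmax,
        baseline=None,
        preload=True,
        verbose="error",
    )
    trials = []
    inv = {code: event_map[name] for name, code in wanted.items()}
    for i in range(len(epochs)):
        label = inv[int(epochs.events[i, 2])]
        trials.append(EEGTrial(data=epochs.get_data()[i], label=label, subject=subject))
    return EEGDataset(
        trials=trials,
        n_channels=raw.info["nchan"],
        n_classes=max(event_map.values()) + 1,
        sampling_rate=float(raw.info["sfreq"]),
    )


def load_dataset(
    path,
    fmt: str = "container",
    event_map: dict | None = None,
    tmin: float = 0.0,
    tmax: float = 4.0,
    subject: str = "S01",
) -> EEGDataset:
    """Load trials from the portable container or a raw EDF/GDF recording."""
    path = Path(path)
    if fmt == "container":
        return _load_container(path)
    if fmt in ("edf", "gdf"):
        return _load_raw_eeg(path, fmt, event_map, tmin, tmax, subject)
    raise ConfigurationError(f"unknown dataset format {fmt!r}")


# ---------------------------------------------------------------------------
# descriptor container


def save_descriptors(
    path, samples, stats: NormalizerStats, seed: int = 0, cfg_hash: str = ""
) -> None:
    samples = list(samples)
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = DESC_FORMAT_VERSION
        d = samples[0].dim if samples else stats.mean.shape[0]
        f.attrs["n_channels"] = d
        f.attrs["n_classes"] = int(max((s.label for s in samples), default=0)) + 1
        _write_provenance(f, seed, cfg_hash)
        f.create_dataset(
            "matrices",
            data=np.stack([s.matrix for s in samples]) if samples else np.zeros((0, d, d)),
            track_times=False,
        )
        f.create_dataset(
            "labels", data=np.asarray([s.label for s in samples], dtype=np.int64),
            track_times=False,
        )
        f.create_dataset(
            "subjects",
            data=np.asarray([s.subject for s in samples], dtype=object),
            dtype=_STR,
            track_times=False,
        )
        f.create_dataset(
            "normalized",
            data=np.asarray([s.normalized for s in samples], dtype=bool),
            track_times=False,
        )
        g = f.create_group("normalizer")
        g.create_dataset("mean", data=stats.mean, track_times=False)
        g.create_dataset("std", data=stats.std, track_times=False)
        g.attrs["n_fitted"] = stats.n_fitted
        g.attrs["epsilon"] = stats.epsilon


def load_descriptors(path):
    path = Path(path)
    with h5py.File(path, "r") as f:
        _check_version(f, DESC_FORMAT_VERSION, path)
        mats = f["matrices"][...]
        labels = f["labels"][...]
        subjects = [s.decode() if isinstance(s, bytes) else str(s) for s in f["subjects"][...]]
        normalized = f["normalized"][...]
        samples = [
            SPDSample(
                matrix=mats[i],
                label=int(labels[i]),
                subject=subjects[i],
                normalized=bool(normalized[i]),
            )
            for i in range(len(labels))
        ]
        g = f["normalizer"]
        stats = NormalizerStats(
            mean=g["mean"][...],
            std=g["std"][...],
            n_fitted=int(g.attrs["n_fitted"]),
            epsilon=float(g.attrs["epsilon"]),
        )
        return samples, stats


# ---------------------------------------------------------------------------
# model container


def save_model(path, params: ModelParams, seed: int = 0, cfg_hash: str = "") -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = MODEL_FORMAT_VERSION
        f.attrs["input_dim"] = params.input_dim
        f.attrs["n_classes"] = params.n_classes
        _write_provenance(f, seed, cfg_hash)
        ext = f.create_group("extractor")
        for i, (w, b) in enumerate(zip(params.extractor.weights, params.extractor.biases)):
            ext.create_dataset(f"w{i}", data=w, track_times=False)
            ext.create_dataset(f"b{i}", data=b, track_times=False)
        clf = f.create_group("classifier")
        for name, arr in zip(("w1", "b1", "w2", "b2"), params.classifier.arrays):
            clf.create_dataset(name, data=arr, track_times=False)
        ss = f.create_group("ss")
        ss.create_dataset("scales", data=params.ss.scales, track_times=False)
        ss.create_dataset("shifts", data=params.ss.shifts, track_times=False)


def load_model(path) -> ModelParams:
    path = Path(path)
    with h5py.File(path, "r") as f:
        _check_version(f, MODEL_FORMAT_VERSION, path)
        ext = f["extractor"]
        weights = [ext[f"w{i}"][...] for i in range(N_CONV)]
        biases = [ext[f"b{i}"][...] for i in range(N_CONV)]
        clf = f["classifier"]
        classifier = ClassifierParams(
            w1=clf["w1"][...], b1=clf["b1"][...], w2=clf["w2"][...], b2=clf["b2"][...]
        )
        ss = SSParams(scales=f["ss"]["scales"][...], shifts=f["ss"]["shifts"][...])
        return ModelParams(
            extractor=FeatureExtractorParams(weights, biases),
            classifier=classifier,
            ss=ss,
            input_dim=int(f.attrs["input_dim"]),
            n_classes=int(f.attrs["n_classes"]),
        )


def artifact_geometry(path) -> tuple[int, int]:
    """(d, K) recorded in any spdcnn artifact, for compatibility checks."""
    with h5py.File(path, "r") as f:
        d = int(f.attrs.get("n_channels", f.attrs.get("input_dim", 0)))
        k = int(f.attrs.get("n_classes", 0))
    return d, k


# ---------------------------------------------------------------------------
# run configuration


_SECTIONS = {
    "generator": {
        "n_subjects",
        "n_classes",
        "n_channels",
        "n_trials_per_class",
        "n_samples",
        "mixing_strength",
        "noise_sd",
        "separation",
    },
    "descriptor": {"epsilon", "norm_scope"},
    "folds": {"n_val", "n_test", "n_folds", "balanced"},
    "training": {f.name for f in dataclasses.fields(TrainingConfig)},
    "evaluation": {"strategies", "shots", "centroids"},
}


class RunConfig:
    """Nested run configuration loaded from YAML; unknown keys are rejected."""

    def __init__(self, mapping: dict | None = None):
        mapping = mapping or {}
        for section, keys in mapping.items():
            if section not in _SECTIONS:
                raise ConfigurationError(f"unknown config section {section!r}")
            unknown = set(keys) - _SECTIONS[section]
            if unknown:
                raise ConfigurationError(
                    f"unknown keys in section {section!r}: {sorted(unknown)}"
                )
        self.mapping = mapping

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls(data)

    def section(self, name: str) -> dict:
        return dict(self.mapping.get(name, {}))

    def training_config(self, seed: int | None = None) -> TrainingConfig:
        kwargs = self.section("training")
        if seed is not None:
            kwargs["seed"] = seed
        return TrainingConfig(**kwargs)

    @property
    def hash(self) -> str:
        return config_hash(self.mapping)
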