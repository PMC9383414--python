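"""The SPD-CNN classifier and its scaling-and-shifting (SS) reparameterization.

Architecture (all convolutions valid, stride 1, kernel 2x2; ReLU after every
conv; one 2x2/stride-2 max-pool between Conv3 and Conv4):

    input d x d -> Conv1(4) -> Conv2(8) -> Conv3(16) -> MaxPool
                -> Conv4(32) -> Conv5(64) -> flatten
                -> FC(32, ReLU) -> FC(K) -> softmax

Each conv layer ``l`` additionally carries one scalar scale ``phi_s1[l]``
and one scalar shift ``phi_s2[l]``:

    SS(X; W, b; s1, s2) = (W * s1) (*) X + (b + s2)

i.e. a plain cross-correlation whose weights are multiplied by the layer
scale and whose biases are incremented by the layer shift.  With scale 1
and shift 0 the network is exactly the plain CNN; the meta phase learns
only these ten scalars.

Forward, backward and initialization are implemented directly in NumPy;
the network is small enough (a few tens of thousands of parameters on
typical channel counts) that this is fast on one CPU.  A finite-difference
test validates the analytic gradients.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .descriptor import SPDSample
from .exceptions import DataError, DimensionError, GeometryError, StateWarning, StateError

__all__ = [
    "CHANNEL_SCHEDULE",
    "FeatureExtractorParams",
    "ClassifierParams",
    "SSParams",
    "ModelParams",
    "feature_geometry",
    "flatten_dim_for",
    "build_params",
    "init_classifier",
    "ss_conv",
    "forward",
    "forward_batch",
    "predict",
    "extractor_features",
    "network_forward_cached",
    "network_backward",
    "Gradients",
    "count_parameters",
    "checksum",
]

#: Output-channel schedule of the five conv layers.
CHANNEL_SCHEDULE = (4, 8, 16, 32, 64)
HIDDEN_WIDTH = 32
N_CONV = 5


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class FeatureExtractorParams:
    """Conv weights/biases Theta: W[l] is (out, in, 2, 2), b[l] is (out,)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "FeatureExtractorParams":
        return FeatureExtractorParams(
            [w.copy() for w in self.weights], [b.copy() for b in self.biases]
        )


@dataclass
class ClassifierParams:
    """Two-layer fully-connected head theta: flatten -> 32 (ReLU) -> K."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    def copy(self) -> "ClassifierParams":
        return ClassifierParams(self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2.copy())

    @property
    def arrays(self) -> list[np.ndarray]:
        return [self.w1, self.b1, self.w2, self.b2]


@dataclass
class SSParams:
    """One (scale, shift) scalar pair per conv layer; identity is (1, 0)."""

    scales: np.ndarray = field(default_factory=lambda: np.ones(N_CONV))
    shifts: np.ndarray = field(default_factory=lambda: np.zeros(N_CONV))

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.scales.shape != (N_CONV,) or self.shifts.shape != (N_CONV,):
            raise DimensionError(f"SS parameters must have one pair per conv layer ({N_CONV})")

    @classmethod
    def identity(cls) -> "SSParams":
        return cls()

    def copy(self) -> "SSParams":
        return SSParams(self.scales.copy(), self.shifts.copy())

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.scales == 1.0) and np.all(self.shifts == 0.0))


@dataclass
class ModelParams:
    """Full model: extractor Theta, classifier theta, SS pair Phi_ss."""

    extractor: FeatureExtractorParams
    classifier: ClassifierParams
    ss: SSParams
    input_dim: int
    n_classes: int

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.extractor.copy(),
            self.classifier.copy(),
            self.ss.copy(),
            self.input_dim,
            self.n_classes,
        )


# ---------------------------------------------------------------------------
# geometry


def feature_geometry(d: int) -> list[int]:
    """Spatial sizes [input, Conv1..Conv3, MaxPool, Conv4, Conv5].

    Each valid 2x2 conv shrinks the side by 1; the pool halves it with
    floor.  Raises :class:`GeometryError` naming the first layer whose
    output would vanish (minimum workable input is d = 9).
    """
    names = ["Conv1", "Conv2", "Conv3", "MaxPool", "Conv4", "Conv5"]
    sizes = [d]
    s = d
    for name in names:
        s = s // 2 if name == "MaxPool" else s - 1
        if s < 1:
            raise GeometryError(
                f"input size d={d} collapses to {s} at {name}; minimum supported d is 9"
            )
        sizes.append(s)
    return sizes


def flatten_dim_for(d: int) -> int:
    """Flattened feature size 64*m*m with m the Conv5 output side."""
    return CHANNEL_SCHEDULE[-1] * feature_geometry(d)[-1] ** 2


def build_params(d: int, K: int, seed: int = 0) -> ModelParams:
    """He-normal initialized parameters for a d x d input and K classes.

    Weights are drawn ``N(0, sqrt(2/fan_in))`` (fan-in mode), biases start
    at zero, SS parameters at identity.  Deterministic given ``seed``.
    """
    if K < 2:
        raise DataError(f"need K >= 2 classes, got {K}")
    flat = flatten_dim_for(d)  # raises GeometryError for d < 9
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    in_ch = 1
    for out_ch in CHANNEL_SCHEDULE:
        fan_in = in_ch * 4
        weights.append(rng.standard_normal((out_ch, in_ch, 2, 2)) * np.sqrt(2.0 / fan_in))
        biases.append(np.zeros(out_ch))
        in_ch = out_ch
    classifier = init_classifier(flat, K, rng)
    return ModelParams(
        extractor=FeatureExtractorParams(weights, biases),
        classifier=classifier,
        ss=SSParams.identity(),
        input_dim=d,
        n_classes=K,
    )


def init_classifier(flatten_dim: int, K: int, rng) -> ClassifierParams:
    """He-normal two-layer head; accepts a Generator or an int seed."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    w1 = rng.standard_normal((flatten_dim, HIDDEN_WIDTH)) * np.sqrt(2.0 / flatten_dim)
    w2 = rng.standard_normal((HIDDEN_WIDTH, K)) * np.sqrt(2.0 / HIDDEN_WIDTH)
    return ClassifierParams(w1=w1, b1=np.zeros(HIDDEN_WIDTH), w2=w2, b2=np.zeros(K))


def count_parameters(params: ModelParams) -> int:
    n = sum(w.size + b.size for w, b in zip(params.extractor.weights, params.extractor.biases))
    n += sum(a.size for a in params.classifier.arrays)
    return n


def checksum(*arrays_or_params) -> str:
    """SHA-256 over the exact bytes of the given arrays / parameter blocks.

    Used by the freeze-contract tests and the INFO logs to prove which
    phases touch which parameters.
    """
    h = hashlib.sha256()
    for obj in arrays_or_params:
        for a in _iter_arrays(obj):
            h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def _iter_arrays(obj):
    if isinstance(obj, np.ndarray):
        yield obj
    elif isinstance(obj, FeatureExtractorParams):
        yield from obj.weights
        yield from obj.biases
    elif isinstance(obj, ClassifierParams):
        yield from obj.arrays
    elif isinstance(obj, SSParams):
        yield obj.scales
        yield obj.shifts
    elif isinstance(obj, ModelParams):
        yield from _iter_arrays(obj.extractor)
        yield from _iter_arrays(obj.classifier)
        yield from _iter_arrays(obj.ss)
    else:
        raise TypeError(f"cannot checksum {type(obj)!r}")


# ---------------------------------------------------------------------------
# primitive layers


def _conv2x2(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid stride-1 cross-correlation with a 2x2 kernel.

    x: (N, Cin, H, W); w: (Cout, Cin, 2, 2) -> (N, Cout, H-1, W-1).
    Written as four shifted contractions, which is fast at these sizes.
    """
    h, wd = x.shape[2], x.shape[3]
    out = np.einsum("ncij,oc->noij", x[:, :, : h - 1, : wd - 1], w[:, :, 0, 0])
    out += np.einsum("ncij,oc->noij", x[:, :, : h - 1, 1:], w[:, :, 0, 1])
    out += np.einsum("ncij,oc->noij", x[:, :, 1:, : wd - 1], w[:, :, 1, 0])
    out += np.einsum("ncij,oc->noij", x[:, :, 1:, 1:], w[:, :, 1, 1])
    return out


def _conv2x2_backward(dout: np.ndarray, x: np.ndarray, w: np.ndarray):
    """Gradients of a valid 2x2 conv: returns (dW, dx)."""
    h, wd = x.shape[2], x.shape[3]
    dw = np.empty_like(w)
    dx = np.zeros_like(x)
    offsets = (
        (0, 0, slice(0, h - 1), slice(0, wd - 1)),
        (0, 1, slice(0, h - 1), slice(1, wd)),
        (1, 0, slice(1, h), slice(0, wd - 1)),
        (1, 1, slice(1, h), slice(1, wd)),
    )
    for di, dj, si, sj in offsets:
        dw[:, :, di, dj] = np.einsum("noij,ncij->oc", dout, x[:, :, si, sj])
        dx[:, :, si, sj] += np.einsum("noij,oc->ncij", dout, w[:, :, di, dj])
    return dw, dx


def ss_conv(
    x: np.ndarray,
    w: np.ndarray,
    b: np.ndarray,
    scale: float = 1.0,
    shift: float = 0.0,
) -> np.ndarray:
    """The SS operation: ``(W * scale) conv X + (b + shift)``.

    Accepts a single map (Cin, H, W) or a batch (N, Cin, H, W).
    """
    for arr in (w, b):
        if not np.all(np.isfinite(arr)):
            raise DataError("non-finite conv parameters")
    if not np.isfinite(scale) or not np.isfinite(shift):
        raise DataError("non-finite SS parameters")
    single = x.ndim == 3
    xb = x[None] if single else x
    out = scale * _conv2x2(xb, w) + (np.asarray(b) + shift)[None, :, None, None]
    return out[0] if single else out


def _pool_forward(x: np.ndarray):
    """2x2 max-pool, stride 2, floor on odd sizes; returns (out, argmax)."""
    n, c, h, wd = x.shape
    h2, w2 = h // 2, wd // 2
    xc = (
        x[:, :, : 2 * h2, : 2 * w2]
        .reshape(n, c, h2, 2, w2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h2, w2, 4)
    )
    idx = xc.argmax(axis=4)
    out = np.take_along_axis(xc, idx[..., None], axis=4)[..., 0]
    return out, idx


def _pool_backward(dout: np.ndarray, idx: np.ndarray, x_shape) -> np.ndarray:
    n, c, h, wd = x_shape
    h2, w2 = h // 2, wd // 2
    dxc = np.zeros((n, c, h2, w2, 4))
    np.put_along_axis(dxc, idx[..., None], dout[..., None], axis=4)
    dx = np.zeros(x_shape)
    dx[:, :, : 2 * h2, : 2 * w2] = (
        dxc.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h2, 2 * w2)
    )
    return dx


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# full network forward / backward


@dataclass
class _Cache:
    """Intermediates kept for the backward pass."""

    conv_inputs: list
    conv_z: list  # plain conv output, before scale/bias
    conv_pre: list  # scale*z + b + shift
    pool_input_shape: tuple | None
    pool_idx: np.ndarray | None
    flat: np.ndarray
    h_pre: np.ndarray
    h: np.ndarray
    probs: np.ndarray


@dataclass
class Gradients:
    """Gradients for every trainable block (callers use the parts they need)."""

    conv_w: list
    conv_b: list
    ss_scales: np.ndarray
    ss_shifts: np.ndarray
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray


def _extractor_forward(params: ModelParams, x: np.ndarray, keep: bool):
    """Conv stack on a batch (N, 1, d, d) -> flat (N, F) [+ cache pieces]."""
    conv_inputs, conv_z, conv_pre = [], [], []
    pool_shape, pool_idx = None, None
    ext, ss = params.extractor, params.ss
    for layer in range(N_CONV):
        if layer == 3:  # pool sits between Conv3 and Conv4
            pool_shape = x.shape
            x, pool_idx = _pool_forward(x)
        if keep:
            conv_inputs.append(x)
        z = _conv2x2(x, ext.weights[layer])
        pre = ss.scales[layer] * z + (ext.biases[layer] + ss.shifts[layer])[None, :, None, None]
        if keep:
            conv_z.append(z)
            conv_pre.append(pre)
        x = np.maximum(pre, 0.0)
    flat = x.reshape(x.shape[0], -1)
    return flat, conv_inputs, conv_z, conv_pre, pool_shape, pool_idx


def extractor_features(params: ModelParams, matrices: np.ndarray) -> np.ndarray:
    """Flattened feature-extractor output for a batch of (d, d) matrices.

    The features depend only on (Theta, Phi_ss); training phases that touch
    just the classifier precompute them once with this function.
    """
    x = np.asarray(matrices, dtype=float)[:, None, :, :]
    flat, *_ = _extractor_forward(params, x, keep=False)
    return flat


def classifier_probs(clf: ClassifierParams, flat: np.ndarray) -> np.ndarray:
    """Softmax class probabilities from precomputed features."""
    h = np.maximum(flat @ clf.w1 + clf.b1, 0.0)
    return _softmax(h @ clf.w2 + clf.b2)


def network_forward_cached(params: ModelParams, matrices: np.ndarray):
    """Full forward on a batch of (d, d) matrices, keeping the cache."""
    x = np.asarray(matrices, dtype=float)[:, None, :, :]
    flat, conv_inputs, conv_z, conv_pre, pool_shape, pool_idx = _extractor_forward(
        params, x, keep=True
    )
    clf = params.classifier
    h_pre = flat @ clf.w1 + clf.b1
    h = np.maximum(h_pre, 0.0)
    probs = _softmax(h @ clf.w2 + clf.b2)
    cache = _Cache(
        conv_inputs=conv_inputs,
        conv_z=conv_z,
        conv_pre=conv_pre,
        pool_input_shape=pool_shape,
        pool_idx=pool_idx,
        flat=flat,
        h_pre=h_pre,
        h=h,
        probs=probs,
    )
    return probs, cache


def network_backward(params: ModelParams, cache: _Cache, dlogits: np.ndarray) -> Gradients:
    """Backpropagate ``dL/dlogits`` through the whole network."""
    clf, ext, ss = params.classifier, params.extractor, params.ss
    dw2 = cache.h.T @ dlogits
    db2 = dlogits.sum(axis=0)
    dh = dlogits @ clf.w2.T
    dh_pre = dh * (cache.h_pre > 0)
    dw1 = cache.flat.T @ dh_pre
    db1 = dh_pre.sum(axis=0)
    dflat = dh_pre @ clf.w1.T

    n = cache.flat.shape[0]
    m = cache.conv_pre[-1].shape[-1]
    dx = dflat.reshape(n, CHANNEL_SCHEDULE[-1], m, m)

    conv_w_grads: list = [None] * N_CONV
    conv_b_grads: list = [None] * N_CONV
    dscales = np.zeros(N_CONV)
    dshifts = np.zeros(N_CONV)
    for layer in range(N_CONV - 1, -1, -1):
        dpre = dx * (cache.conv_pre[layer] > 0)
        dscales[layer] = float(np.sum(dpre * cache.conv_z[layer]))
        dshifts[layer] = float(np.sum(dpre))
        conv_b_grads[layer] = dpre.sum(axis=(0, 2, 3))
        dz = ss.scales[layer] * dpre
        dw, dx = _conv2x2_backward(dz, cache.conv_inputs[layer], ext.weights[layer])
        conv_w_grads[layer] = dw
        if layer == 3:  # undo the pool that precedes Conv4
            dx = _pool_backward(dx, cache.pool_idx, cache.pool_input_shape)
    return Gradients(
        conv_w=conv_w_grads,
        conv_b=conv_b_grads,
        ss_scales=dscales,
        ss_shifts=dshifts,
        w1=dw1,
        b1=db1,
        w2=dw2,
        b2=db2,
    )


# ---------------------------------------------------------------------------
# public inference API


def _as_matrix(params: ModelParams, c, on_unnormalized: str) -> np.ndarray:
    if isinstance(c, SPDSample):
        if not c.normalized:
            msg = "descriptor has not been normalized; the network expects C* inputs"
            if on_unnormalized == "error":
                raise StateError(msg)
            if on_unnormalized == "warn":
                warnings.warn(msg, StateWarning, stacklevel=3)
        mat = c.matrix
    else:
        mat = np.asarray(c, dtype=float)
    if mat.shape != (params.input_dim, params.input_dim):
        raise DimensionError(
            f"descriptor is {mat.shape}, model expects "
            f"({params.input_dim}, {params.input_dim})"
        )
    return mat


def forward(params: ModelParams, c, on_unnormalized: str = "warn") -> np.ndarray:
    """Class-probability vector for one descriptor (SPDSample or (d, d) array)."""
    mat = _as_matrix(params, c, on_unnormalized)
    flat = extractor_features(params, mat[None])
    return classifier_probs(params.classifier, flat)[0]


def forward_batch(params: ModelParams, matrices: np.ndarray) -> np.ndarray:
    """Class probabilities (N, K) for a stacked batch of (d, d) matrices."""
    flat = extractor_features(params, matrices)
    return classifier_probs(params.classifier, flat)


def predict(params: ModelParams, c, on_unnormalized: str = "warn") -> int:
    """Argmax class; ties break toward the lowest class index."""
    return int(np.argmax(forward(params, c, on_unnormalized)))
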