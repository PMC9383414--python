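"""Three-phase meta-transfer training of the SPD-CNN.

Phase 1 (pre-train): all training subjects' descriptors are pooled and the
full network F(Theta, theta) is trained jointly by Adam on cross-entropy.

Phase 2 (meta-update): the classifier theta is re-initialized; the raw conv
weights Theta_pre are frozen.  Subject-specific N-way K-shot tasks are
sampled from the training subjects; for each task a copy of theta is
adapted on the support set by a few plain gradient steps (inner loop), and
the query losses summed over a meta-batch drive an Adam step on the ten SS
scalars Phi_ss only (first-order meta-gradient).  After every epoch the
candidate Phi_ss is scored by mean query accuracy over validation-subject
tasks, and the best-scoring snapshot — including the identity
initialization evaluated before the first update — is kept as Theta_meta =
(Theta_pre, Phi_ss*).

Phase 3 (domain adaptation): for a new user, the feature extractor
(Theta_meta, i.e. conv weights and SS scalars) stays fixed and only the
classifier theta is fine-tuned on the user's few labeled support trials.

Learning rates follow the shared schedule: base 0.001, multiplied by 0.99
every 10 epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .descriptor import SPDSample
from .exceptions import ConfigurationError, DataError, SamplingError
from .network import (
    ClassifierParams,
    ModelParams,
    build_params,
    checksum,
    classifier_probs,
    extractor_features,
    init_classifier,
    network_backward,
    network_forward_cached,
)
from .sampler import EpisodicTask, build_meta_batches, sample_tasks_evenly

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "cross_entropy",
    "effective_lr",
    "meta_loss",
    "pretrain",
    "inner_adapt",
    "meta_update",
    "domain_adapt",
    "PretrainResult",
    "MetaResult",
    "group_by_subject",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the three phases.

    Learning rates alpha (pre-train), lambda (SS meta-update) and beta
    (domain adaptation) all default to 0.001 and decay by 1% every 10
    epochs.  Episodes default to 4-way 5-shot with 10 query samples per
    class; one meta loop uses 60 tasks in 12 meta-batches of 5, with 30
    validation tasks per epoch.
    """

    lr_pretrain: float = 0.001
    lr_ss: float = 0.001
    lr_adapt: float = 0.001
    lr_decay: float = 0.99
    decay_every: int = 10
    pretrain_epochs: int = 50
    meta_epochs: int = 40
    batch_size: int = 64
    inner_steps: int = 5
    lr_inner: float = 0.01
    n_way: int = 4
    k_shot: int = 5
    n_query: int = 10
    tasks_per_loop: int = 60
    meta_batch_size: int = 5
    n_val_tasks: int = 30
    adapt_epochs: int = 50
    meta_update_theta: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lr_pretrain", "lr_ss", "lr_adapt", "lr_inner"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0 < self.lr_decay <= 1):
            raise ConfigurationError("lr_decay must lie in (0, 1]")
        for name in ("pretrain_epochs", "meta_epochs", "adapt_epochs"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")


def effective_lr(base: float, epoch: int, decay: float = 0.99, every: int = 10) -> float:
    """Learning rate at a given epoch: ``base * decay**(epoch // every)``."""
    return base * decay ** (epoch // every)


def cross_entropy(probs, label) -> float:
    """Cross-entropy ``-log p[label]`` with the probability floored at 1e-12.

    Accepts one probability vector with an int label, or a batch (N, K)
    with N labels, in which case the per-sample losses are averaged.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim == 1:
        probs = probs[None]
        labels = np.asarray([label])
    else:
        labels = np.asarray(label)
    if np.any(labels < 0) or np.any(labels >= probs.shape[1]):
        raise DataError(f"label outside 0..{probs.shape[1] - 1}")
    picked = probs[np.arange(len(labels)), labels]
    return float(-np.log(np.maximum(picked, 1e-12)).mean())


def meta_loss(task_losses) -> float:
    """The meta objective: sum of per-task query losses."""
    losses = list(task_losses)
    if not losses:
        raise DataError("meta_loss needs at least one task loss")
    return float(np.sum(losses))


def group_by_subject(samples) -> dict[str, list]:
    by_subject: dict[str, list] = {}
    for s in samples:
        by_subject.setdefault(s.subject, []).append(s)
    return by_subject


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam over a fixed list of parameter arrays, updated in place."""

    def __init__(self, arrays, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays, grads, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            a -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# classifier-only gradients (the inner loop and domain adaptation only ever
# touch theta, so they work on precomputed extractor features)


def _clf_loss_and_grads(clf: ClassifierParams, feats: np.ndarray, labels: np.ndarray):
    h_pre = feats @ clf.w1 + clf.b1
    h = np.maximum(h_pre, 0.0)
    logits = h @ clf.w2 + clf.b2
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = float(-np.log(np.maximum(probs[np.arange(n), labels], 1e-12)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    dw2 = h.T @ dlogits
    db2 = dlogits.sum(axis=0)
    dh_pre = (dlogits @ clf.w2.T) * (h_pre > 0)
    dw1 = feats.T @ dh_pre
    db1 = dh_pre.sum(axis=0)
    return loss, [dw1, db1, dw2, db2]


def _matrices_and_labels(samples):
    mats = np.stack([s.matrix if isinstance(s, SPDSample) else np.asarray(s) for s in samples])
    labels = np.asarray([s.label for s in samples])
    return mats, labels


def _remap_labels(labels: np.ndarray, classes) -> np.ndarray:
    """Map absolute class ids onto 0..n_way-1 slots of the task's class tuple."""
    lut = {c: i for i, c in enumerate(classes)}
    return np.asarray([lut[int(l)] for l in labels])


# ---------------------------------------------------------------------------
# phase 1: pre-train


@dataclass
class PretrainResult:
    params: ModelParams
    loss_history: list[float] = field(default_factory=list)


def pretrain(
    samples,
    config: TrainingConfig,
    params: ModelParams | None = None,
    n_classes: int | None = None,
) -> PretrainResult:
    """Joint Adam training of (Theta, theta) on pooled training-subject data.

    SS parameters stay at identity and are never updated here.  Returns the
    trained parameters and the per-epoch mean loss trace.  Deterministic
    given ``config.seed``.
    """
    samples = list(samples)
    if not samples:
        raise DataError("pretrain needs at least one sample")
    mats, labels = _matrices_and_labels(samples)
    d = mats.shape[1]
    k = n_classes if n_classes is not None else int(labels.max()) + 1
    if params is None:
        params = build_params(d, k, seed=config.seed)
    arrays = (
        params.extractor.weights
        + params.extractor.biases
        + params.classifier.arrays
    )
    opt = Adam(arrays)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    history: list[float] = []
    n = len(samples)
    for epoch in range(config.pretrain_epochs):
        lr = effective_lr(config.lr_pretrain, epoch, config.lr_decay, config.decay_every)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            probs, cache = network_forward_cached(params, mats[idx])
            nb = len(idx)
            loss = float(
                -np.log(np.maximum(probs[np.arange(nb), labels[idx]], 1e-12)).mean()
            )
            dlogits = probs.copy()
            dlogits[np.arange(nb), labels[idx]] -= 1.0
            dlogits /= nb
            g = network_backward(params, cache, dlogits)
            opt.step(arrays, g.conv_w + g.conv_b + [g.w1, g.b1, g.w2, g.b2], lr)
            epoch_loss += loss * nb
        history.append(epoch_loss / n)
        logger.info(
            "pretrain epoch %d/%d lr=%.2e loss=%.4f theta_ss=%s",
            epoch + 1,
            config.pretrain_epochs,
            lr,
            history[-1],
            checksum(params.ss)[:8],
        )
    return PretrainResult(params=params, loss_history=history)


# ---------------------------------------------------------------------------
# inner loop


def inner_adapt(
    task: EpisodicTask,
    params: ModelParams,
    theta_init: ClassifierParams,
    inner_steps: int = 5,
    lr_inner: float = 0.01,
    _support_feats: np.ndarray | None = None,
    _query_feats: np.ndarray | None = None,
):
    """Adapt a copy of theta on the task's support set; score on the query set.

    Runs ``inner_steps`` full-batch plain gradient steps on the support
    cross-entropy, touching only the classifier copy; Theta and Phi_ss are
    read-only.  Returns ``(theta_task, query_loss)``.
    """
    if not task.support:
        raise SamplingError("task has an empty support set")
    s_mats, s_labels = _matrices_and_labels(task.support)
    q_mats, q_labels = _matrices_and_labels(task.query)
    if task.classes:
        s_labels = _remap_labels(s_labels, task.classes)
        q_labels = _remap_labels(q_labels, task.classes)
    sf = _support_feats if _support_feats is not None else extractor_features(params, s_mats)
    qf = _query_feats if _query_feats is not None else extractor_features(params, q_mats)
    theta = theta_init.copy()
    for _ in range(inner_steps):
        _, grads = _clf_loss_and_grads(theta, sf, s_labels)
        for a, g in zip(theta.arrays, grads):
            a -= lr_inner * g
    q_probs = classifier_probs(theta, qf)
    q_loss = cross_entropy(q_probs, q_labels)
    return theta, q_loss


# ---------------------------------------------------------------------------
# phase 2: meta-update of the SS parameters


@dataclass
class MetaResult:
    params: ModelParams  # frozen Theta_pre + best Phi_ss + the deployment theta_pre
    val_history: list[float] = field(default_factory=list)
    meta_loss_history: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 0 = the pre-update (identity) snapshot


def _task_accuracy(theta: ClassifierParams, qf: np.ndarray, q_labels: np.ndarray) -> float:
    preds = classifier_probs(theta, qf).argmax(axis=1)
    return float(np.mean(preds == q_labels))


def _adapt_on_features(
    theta_init: ClassifierParams, feats: np.ndarray, labels: np.ndarray, config: TrainingConfig
) -> ClassifierParams:
    """The deployment fine-tuning loop (Adam on theta only), on fixed features."""
    theta = theta_init.copy()
    opt = Adam(theta.arrays)
    for epoch in range(config.adapt_epochs):
        lr = effective_lr(config.lr_adapt, epoch, config.lr_decay, config.decay_every)
        _, grads = _clf_loss_and_grads(theta, feats, labels)
        opt.step(theta.arrays, grads, lr)
    return theta


def _validation_accuracy(
    params: ModelParams,
    theta_deploy: ClassifierParams,
    tasks,
    config: TrainingConfig,
):
    """Mean query accuracy (and its standard error) over a fixed validation
    task set, scored the way a candidate Phi_ss will actually be deployed:
    classifier fine-tuned from ``theta_deploy`` on each task's support set.
    Using the same tasks for every candidate makes snapshot comparisons
    paired, so selection reacts to real differences rather than task-draw
    noise."""
    accs = []
    for task in tasks:
        s_mats, s_labels = _matrices_and_labels(task.support)
        q_mats, q_labels = _matrices_and_labels(task.query)
        if task.classes:
            s_labels = _remap_labels(s_labels, task.classes)
            q_labels = _remap_labels(q_labels, task.classes)
        sf = extractor_features(params, s_mats)
        qf = extractor_features(params, q_mats)
        theta = _adapt_on_features(theta_deploy, sf, s_labels, config)
        accs.append(_task_accuracy(theta, qf, q_labels))
    mean = float(np.mean(accs))
    se = float(np.std(accs, ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0
    return mean, se


def meta_update(
    pre_params: ModelParams,
    train_samples,
    val_samples,
    config: TrainingConfig,
) -> MetaResult:
    """Learn the SS scalars by first-order MAML over subject-specific tasks.

    The classifier is randomly re-initialized (theta*); raw conv weights of
    the pre-trained extractor are frozen throughout (unless
    ``config.meta_update_theta`` deliberately enables the fully-unfrozen
    variant).  One Adam step on Phi_ss per meta-batch, learning rate
    lambda with the shared decay schedule; the returned Phi_ss is the
    snapshot with the highest validation-task accuracy, the identity
    initialization included as a candidate; a learned snapshot displaces the
    identity only when its gain exceeds the standard error of the baseline
    validation estimate (a one-standard-error selection rule, guarding
    against winner's-curse selection on few validation subjects).
    Candidates are scored with the
    deployment procedure (classifier fine-tuned from the pre-trained theta
    on each validation task's support set), and the returned model carries
    that deployment classifier; the transient random theta* only seeds the
    inner loops that generate the meta-gradient.
    """
    val_by_subject = group_by_subject(val_samples)
    if not val_by_subject:
        raise ConfigurationError("meta_update requires validation-subject samples")
    train_by_subject = group_by_subject(train_samples)
    if not train_by_subject:
        raise ConfigurationError("meta_update requires training-subject samples")

    params = replace(
        pre_params.copy(),
        classifier=init_classifier(
            pre_params.classifier.w1.shape[0],
            pre_params.n_classes,
            np.random.default_rng(np.random.SeedSequence([config.seed, 2])),
        ),
    )
    theta_star = params.classifier
    ss_arrays = [params.ss.scales, params.ss.shifts]
    theta_arrays = params.extractor.weights + params.extractor.biases
    opt_arrays = ss_arrays + (theta_arrays if config.meta_update_theta else [])
    opt = Adam(opt_arrays)
    train_subjects = sorted(train_by_subject)

    theta_deploy = pre_params.classifier.copy()
    best_ss = params.ss.copy()
    best_extractor = params.extractor.copy() if config.meta_update_theta else None
    val_tasks = sample_tasks_evenly(
        val_by_subject,
        sorted(val_by_subject),
        config.n_val_tasks,
        config.n_way,
        config.k_shot,
        config.n_query,
        np.random.default_rng(np.random.SeedSequence([config.seed, 3])),
    )
    val0, se0 = _validation_accuracy(params, theta_deploy, val_tasks, config)
    val_history = [val0]
    # conservative selection: a learned Phi_ss replaces the identity only when
    # its validation gain exceeds the standard error of the baseline estimate
    best_val, best_epoch = val0 + se0, 0
    loss_history: list[float] = []

    for epoch in range(config.meta_epochs):
        lr = effective_lr(config.lr_ss, epoch, config.lr_decay, config.decay_every)
        rng_tasks = np.random.default_rng(np.random.SeedSequence([config.seed, 4, epoch]))
        tasks = sample_tasks_evenly(
            train_by_subject,
            train_subjects,
            config.tasks_per_loop,
            config.n_way,
            config.k_shot,
            config.n_query,
            rng_tasks,
        )
        batches = build_meta_batches(tasks, config.meta_batch_size)
        epoch_meta_loss = 0.0
        for batch in batches:
            dscales = np.zeros_like(params.ss.scales)
            dshifts = np.zeros_like(params.ss.shifts)
            dtheta = [np.zeros_like(a) for a in theta_arrays] if config.meta_update_theta else None
            batch_losses = []
            for task in batch:
                s_mats, _ = _matrices_and_labels(task.support)
                q_mats, q_labels = _matrices_and_labels(task.query)
                if task.classes:
                    q_labels = _remap_labels(q_labels, task.classes)
                sf = extractor_features(params, s_mats)
                theta_task, _ = inner_adapt(
                    task,
                    params,
                    theta_star,
                    config.inner_steps,
                    config.lr_inner,
                    _support_feats=sf,
                    _query_feats=extractor_features(params, q_mats),
                )
                # first-order meta-gradient of the query loss w.r.t. Phi_ss
                task_params = replace(params, classifier=theta_task)
                probs, cache = network_forward_cached(task_params, q_mats)
                nq = len(q_labels)
                batch_losses.append(
                    float(-np.log(np.maximum(probs[np.arange(nq), q_labels], 1e-12)).mean())
                )
                dlogits = probs.copy()
                dlogits[np.arange(nq), q_labels] -= 1.0
                dlogits /= nq
                g = network_backward(task_params, cache, dlogits)
                dscales += g.ss_scales
                dshifts += g.ss_shifts
                if dtheta is not None:
                    for acc, gw in zip(dtheta, g.conv_w + g.conv_b):
                        acc += gw
            grads = [dscales, dshifts] + (dtheta if dtheta is not None else [])
            opt.step(opt_arrays, grads, lr)
            epoch_meta_loss += meta_loss(batch_losses)
        loss_history.append(epoch_meta_loss)
        val_acc, _ = _validation_accuracy(params, theta_deploy, val_tasks, config)
        val_history.append(val_acc)
        if val_acc > best_val:
            best_val, best_epoch = val_acc, epoch + 1
            best_ss = params.ss.copy()
            if config.meta_update_theta:
                best_extractor = params.extractor.copy()
        logger.info(
            "meta epoch %d/%d lr=%.2e meta_loss=%.3f val_acc=%.3f conv=%s",
            epoch + 1,
            config.meta_epochs,
            lr,
            epoch_meta_loss,
            val_acc,
            checksum(params.extractor)[:8],
        )

    out = params.copy()
    out.ss = best_ss
    out.classifier = theta_deploy  # carried forward for deployment fine-tuning
    if best_extractor is not None:
        out.extractor = best_extractor
    return MetaResult(
        params=out,
        val_history=val_history,
        meta_loss_history=loss_history,
        best_epoch=best_epoch,
    )


# ---------------------------------------------------------------------------
# phase 3: per-user domain adaptation


def domain_adapt(
    params: ModelParams,
    user_support,
    config: TrainingConfig,
    theta_init: ClassifierParams | None = None,
) -> ModelParams:
    """Fine-tune only the classifier on one user's support set.

    The feature extractor — conv weights *and* SS scalars — is fixed;
    ``adapt_epochs`` full-support Adam passes at learning rate beta with
    the shared decay schedule.  Returns a model whose extractor arrays are
    the very same objects as the input's (bit-unchanged) with the adapted
    classifier swapped in.
    """
    support = list(user_support)
    if not support:
        raise SamplingError("domain adaptation needs a nonempty support set")
    mats, labels = _matrices_and_labels(support)
    classes = tuple(sorted(set(int(l) for l in labels)))
    if len(classes) == params.n_classes and classes != tuple(range(params.n_classes)):
        labels = _remap_labels(labels, classes)
    theta = (theta_init or init_classifier(
        params.classifier.w1.shape[0],
        params.n_classes,
        np.random.default_rng(np.random.SeedSequence([config.seed, 5])),
    )).copy()
    feats = extractor_features(params, mats)
    opt = Adam(theta.arrays)
    for epoch in range(config.adapt_epochs):
        lr = effective_lr(config.lr_adapt, epoch, config.lr_decay, config.decay_every)
        _, grads = _clf_loss_and_grads(theta, feats, labels)
        opt.step(theta.arrays, grads, lr)
    return replace(params, classifier=theta)
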