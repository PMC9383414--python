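"""Loss closed forms, schedule, phase freeze contracts, learning behavior."""

import dataclasses

import numpy as np
import pytest

from spdcnn.descriptor import describe_dataset
from spdcnn.exceptions import ConfigurationError, DataError
from spdcnn.network import build_params, checksum, forward_batch
from spdcnn.sampler import sample_task
from spdcnn.training import (
    TrainingConfig,
    cross_entropy,
    domain_adapt,
    effective_lr,
    group_by_subject,
    inner_adapt,
    meta_loss,
    meta_update,
    pretrain,
)


@pytest.fixture(scope="module")
def fast_cfg():
    return TrainingConfig(
        pretrain_epochs=3,
        meta_epochs=2,
        tasks_per_loop=6,
        meta_batch_size=3,
        n_val_tasks=4,
        adapt_epochs=10,
        k_shot=5,
        n_query=5,
        seed=0,
    )


@pytest.fixture(scope="module")
def study_samples(multi_subject_study):
    samples, _ = describe_dataset(multi_subject_study)
    return group_by_subject(samples)


class TestCrossEntropy:
    def test_uniform_is_log_k(self):
        assert cross_entropy(np.full(4, 0.25), 0) == pytest.approx(np.log(4), abs=1e-9)

    def test_certain_prediction_is_zero(self):
        assert cross_entropy(np.array([0.0, 1.0]), 1) == pytest.approx(0.0, abs=1e-9)

    def test_inverse_e_is_one(self):
        p = np.exp(-1.0)
        probs = np.array([p, 1 - p])
        assert cross_entropy(probs, 0) == pytest.approx(1.0, abs=1e-9)

    def test_batch_is_mean(self):
        probs = np.array([[0.5, 0.5], [0.25, 0.75]])
        expected = (-np.log(0.5) - np.log(0.75)) / 2
        assert cross_entropy(probs, np.array([0, 1])) == pytest.approx(expected)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(DataError):
            cross_entropy(np.full(4, 0.25), 7)


class TestMetaLoss:
    def test_sum(self):
        assert meta_loss([0.5, 1.5]) == 2.0
        assert meta_loss([0.0]) == 0.0

    def test_partition_additivity(self, rng):
        losses = list(rng.uniform(0, 2, 60))
        batched = sum(meta_loss(losses[i : i + 5]) for i in range(0, 60, 5))
        assert batched == pytest.approx(meta_loss(losses))

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            meta_loss([])


class TestSchedule:
    def test_one_percent_drop_every_ten_epochs(self):
        for k in range(5):
            assert effective_lr(0.001, 10 * k) == pytest.approx(0.001 * 0.99**k)
        assert effective_lr(0.001, 9) == 0.001
        assert effective_lr(0.001, 10) == pytest.approx(0.00099)


class TestPretrain:
    def test_zero_learning_rate_keeps_parameters(self, study_samples, fast_cfg):
        samples = [s for group in study_samples.values() for s in group]
        cfg = dataclasses.replace(fast_cfg, lr_pretrain=0.0, pretrain_epochs=1)
        init = build_params(12, 4, seed=0)
        before = checksum(init)
        result = pretrain(samples, cfg, params=init)
        assert checksum(result.params) == before

    def test_initial_loss_near_log_k_for_zero_params(self, study_samples, fast_cfg):
        samples = [s for group in study_samples.values() for s in group]
        params = build_params(12, 4, seed=0)
        for w, b in zip(params.extractor.weights, params.extractor.biases):
            w[:] = 0
            b[:] = 0
        for a in params.classifier.arrays:
            a[:] = 0
        cfg = dataclasses.replace(fast_cfg, lr_pretrain=0.0, pretrain_epochs=1)
        result = pretrain(samples, cfg, params=params)
        assert result.loss_history[0] == pytest.approx(np.log(4), abs=1e-9)

    def test_ss_never_touched_and_loss_decreases(self, study_samples, fast_cfg):
        samples = [s for group in study_samples.values() for s in group]
        params = build_params(12, 4, seed=1)
        ss_before = checksum(params.ss)
        result = pretrain(samples, fast_cfg, params=params)
        assert checksum(result.params.ss) == ss_before
        assert result.loss_history[-1] < result.loss_history[0]

    def test_empty_data_rejected(self, fast_cfg):
        with pytest.raises(DataError):
            pretrain([], fast_cfg)


class TestInnerAdapt:
    def _task(self, study_samples, subject="S01"):
        return sample_task(study_samples[subject], 4, 5, 5, seed=3, subject=subject)

    def test_zero_steps_is_noop(self, study_samples):
        params = build_params(12, 4, seed=2)
        task = self._task(study_samples)
        theta, loss = inner_adapt(task, params, params.classifier, inner_steps=0)
        assert checksum(theta) == checksum(params.classifier)
        assert loss > 0

    def test_support_loss_decreases(self, study_samples):
        params = build_params(12, 4, seed=2)
        task = self._task(study_samples)
        # query := support to read the adapted support loss directly
        probe = dataclasses.replace(task, query=task.support)
        _, loss0 = inner_adapt(probe, params, params.classifier, inner_steps=0)
        _, loss20 = inner_adapt(probe, params, params.classifier, inner_steps=20)
        assert loss20 < loss0

    def test_extractor_frozen(self, study_samples):
        params = build_params(12, 4, seed=2)
        task = self._task(study_samples)
        before = checksum(params.extractor, params.ss)
        inner_adapt(task, params, params.classifier, inner_steps=5)
        assert checksum(params.extractor, params.ss) == before


class TestMetaUpdate:
    def _split(self, study_samples):
        subjects = sorted(study_samples)
        train = [s for subj in subjects[:3] for s in study_samples[subj]]
        val = [s for subj in subjects[3:] for s in study_samples[subj]]
        return train, val

    def test_zero_meta_lr_keeps_identity_ss(self, study_samples, fast_cfg):
        train, val = self._split(study_samples)
        pre = pretrain(train, fast_cfg)
        cfg = dataclasses.replace(fast_cfg, lr_ss=0.0)
        meta = meta_update(pre.params, train, val, cfg)
        assert meta.params.ss.is_identity

    def test_conv_weights_frozen_through_meta_phase(self, study_samples, fast_cfg):
        train, val = self._split(study_samples)
        pre = pretrain(train, fast_cfg)
        conv_before = checksum(pre.params.extractor)
        meta = meta_update(pre.params, train, val, fast_cfg)
        assert checksum(pre.params.extractor) == conv_before
        assert checksum(meta.params.extractor) == conv_before

    def test_validation_history_includes_initial_snapshot(self, study_samples, fast_cfg):
        train, val = self._split(study_samples)
        pre = pretrain(train, fast_cfg)
        meta = meta_update(pre.params, train, val, fast_cfg)
        assert len(meta.val_history) == fast_cfg.meta_epochs + 1
        assert 0 <= meta.best_epoch <= fast_cfg.meta_epochs

    def test_missing_validation_subjects_rejected(self, study_samples, fast_cfg):
        train, _ = self._split(study_samples)
        pre = pretrain(train, fast_cfg)
        with pytest.raises(ConfigurationError):
            meta_update(pre.params, train, [], fast_cfg)


class TestDomainAdapt:
    def test_zero_lr_keeps_theta(self, study_samples, fast_cfg):
        params = build_params(12, 4, seed=3)
        task = sample_task(study_samples["S01"], 4, 5, 5, seed=1, subject="S01")
        cfg = dataclasses.replace(fast_cfg, lr_adapt=0.0)
        adapted = domain_adapt(params, task.support, cfg, theta_init=params.classifier)
        assert checksum(adapted.classifier) == checksum(params.classifier)

    def test_extractor_bit_unchanged(self, study_samples, fast_cfg):
        params = build_params(12, 4, seed=3)
        task = sample_task(study_samples["S01"], 4, 5, 5, seed=1, subject="S01")
        before = checksum(params.extractor, params.ss)
        adapted = domain_adapt(params, task.support, fast_cfg)
        assert checksum(adapted.extractor, adapted.ss) == before
        # the returned model shares the very same extractor arrays
        assert adapted.extractor is params.extractor

    def test_adaptation_fits_support(self, study_samples, fast_cfg):
        """After adaptation the classifier predicts its own support set well."""
        params = build_params(12, 4, seed=3)
        task = sample_task(study_samples["S01"], 4, 5, 5, seed=1, subject="S01")
        cfg = dataclasses.replace(fast_cfg, adapt_epochs=100)
        adapted = domain_adapt(params, task.support, cfg)
        mats = np.stack([s.matrix for s in task.support])
        labels = np.array([s.label for s in task.support])
        acc = np.mean(forward_batch(adapted, mats).argmax(1) == labels)
        assert acc >= 0.75

    def test_empty_support_rejected(self, fast_cfg):
        params = build_params(12, 4, seed=3)
        with pytest.raises(Exception):
            domain_adapt(params, [], fast_cfg)
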