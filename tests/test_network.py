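"""Network geometry, SS algebra, forward contracts and gradient correctness."""

import numpy as np
import pytest

from spdcnn.descriptor import SPDSample
from spdcnn.exceptions import GeometryError, StateWarning
from spdcnn.network import (
    CHANNEL_SCHEDULE,
    SSParams,
    build_params,
    checksum,
    count_parameters,
    feature_geometry,
    flatten_dim_for,
    forward,
    forward_batch,
    network_backward,
    network_forward_cached,
    predict,
    ss_conv,
)


class TestGeometry:
    @pytest.mark.parametrize(
        "d,sizes,flat",
        [
            (22, [22, 21, 20, 19, 9, 8, 7], 64 * 49),
            (12, [12, 11, 10, 9, 4, 3, 2], 256),
            (9, [9, 8, 7, 6, 3, 2, 1], 64),
        ],
    )
    def test_spatial_sizes_and_flatten(self, d, sizes, flat):
        assert feature_geometry(d) == sizes
        assert flatten_dim_for(d) == flat

    def test_too_small_input_names_offending_layer(self):
        with pytest.raises(GeometryError, match="Conv5"):
            feature_geometry(8)

    def test_parameter_count_matches_arithmetic(self):
        """Total learnable count recomputed from the layer schedule."""
        d, k = 22, 4
        conv = 0
        in_ch = 1
        for out_ch in CHANNEL_SCHEDULE:
            conv += out_ch * in_ch * 4 + out_ch
            in_ch = out_ch
        assert conv == 11020
        flat = flatten_dim_for(d)
        fc = flat * 32 + 32 + 32 * k + k
        params = build_params(d, k, seed=0)
        assert count_parameters(params) == conv + fc == 111536

    def test_build_is_deterministic(self):
        assert checksum(build_params(12, 4, seed=5)) == checksum(build_params(12, 4, seed=5))
        assert checksum(build_params(12, 4, seed=5)) != checksum(build_params(12, 4, seed=6))


class TestSSConv:
    def test_identity_equals_plain_convolution(self, rng):
        w = rng.standard_normal((3, 2, 2, 2))
        b = rng.standard_normal(3)
        x = rng.standard_normal((2, 5, 5))
        plain = ss_conv(x, w, b, 1.0, 0.0)
        again = ss_conv(x, w, b)
        np.testing.assert_allclose(plain, again, atol=1e-12)

    def test_hand_computed_value(self):
        """All-ones 2x2 kernel on an all-ones 2x2 input, scale 3, shift 0.5."""
        w = np.ones((1, 1, 2, 2))
        b = np.ones(1)
        x = np.ones((1, 2, 2))
        out = ss_conv(x, w, b, scale=3.0, shift=0.5)
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == pytest.approx(4 * 3 + 1.5)

    def test_zero_scale_annihilates_input(self, rng):
        w = rng.standard_normal((4, 3, 2, 2))
        b = rng.standard_normal(4)
        x1 = rng.standard_normal((3, 6, 6))
        x2 = rng.standard_normal((3, 6, 6))
        o1 = ss_conv(x1, w, b, scale=0.0, shift=0.25)
        o2 = ss_conv(x2, w, b, scale=0.0, shift=0.25)
        np.testing.assert_array_equal(o1, o2)
        np.testing.assert_allclose(o1, (b + 0.25)[:, None, None] * np.ones_like(o1))


class TestForward:
    def test_output_is_probability_vector(self, rng):
        params = build_params(12, 4, seed=0)
        c = rng.standard_normal((12, 12))
        probs = forward(params, (c + c.T) / 2)
        assert probs.shape == (4,)
        assert np.all(probs >= 0)
        assert abs(probs.sum() - 1.0) < 1e-9

    def test_zero_parameters_give_uniform_output(self):
        params = build_params(12, 4, seed=0)
        for w, b in zip(params.extractor.weights, params.extractor.biases):
            w[:] = 0
            b[:] = 0
        for a in params.classifier.arrays:
            a[:] = 0
        probs = forward(params, np.eye(12))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_bit_identical_across_runs(self, rng):
        params = build_params(12, 4, seed=3)
        c = rng.standard_normal((12, 12))
        np.testing.assert_array_equal(forward(params, c), forward(params, c))

    def test_ss_folds_into_weights(self, rng):
        """SS with (s1, s2) equals a plain CNN whose weights are W*s1 and
        biases b+s2 — so identity SS is exactly the plain network."""
        params = build_params(12, 4, seed=1)
        assert params.ss.is_identity
        ssed = params.copy()
        ssed.ss = SSParams(scales=rng.uniform(0.5, 1.5, 5), shifts=rng.uniform(-0.3, 0.3, 5))
        folded = ssed.copy()
        for layer in range(5):
            folded.extractor.weights[layer] *= ssed.ss.scales[layer]
            folded.extractor.biases[layer] += ssed.ss.shifts[layer]
        folded.ss = SSParams.identity()
        for _ in range(100):
            c = rng.standard_normal((12, 12))
            np.testing.assert_allclose(
                forward(ssed, c), forward(folded, c), atol=1e-10
            )

    def test_not_permutation_invariant(self, rng):
        """Channel order is meaningful to the conv stack."""
        params = build_params(12, 4, seed=2)
        c = rng.standard_normal((12, 12))
        c = c @ c.T
        perm = rng.permutation(12)
        assert not np.allclose(forward(params, c), forward(params, c[perm][:, perm]))

    def test_unnormalized_sample_warns(self):
        params = build_params(12, 4, seed=0)
        raw = SPDSample(np.eye(12), 0, "S", normalized=False)
        with pytest.warns(StateWarning):
            forward(params, raw)

    def test_batch_matches_single(self, rng):
        params = build_params(12, 4, seed=4)
        mats = rng.standard_normal((6, 12, 12))
        batch = forward_batch(params, mats)
        for i in range(6):
            np.testing.assert_allclose(batch[i], forward(params, mats[i]), atol=1e-12)


class TestPredict:
    def test_argmax_with_tie_toward_lowest_index(self):
        params = build_params(12, 4, seed=0)
        for w, b in zip(params.extractor.weights, params.extractor.biases):
            w[:] = 0
            b[:] = 0
        for a in params.classifier.arrays:
            a[:] = 0
        # uniform probabilities -> class 0 by the tie rule
        assert predict(params, np.eye(12)) == 0

    def test_argmax_of_forward(self, rng):
        params = build_params(12, 4, seed=7)
        c = rng.standard_normal((12, 12))
        assert predict(params, c) == int(np.argmax(forward(params, c)))


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """Analytic gradients vs central differences on every block."""
        d, k, n = 9, 3, 3
        params = build_params(d, k, seed=1)
        params.ss.scales[:] = rng.uniform(0.5, 1.5, 5)
        params.ss.shifts[:] = rng.uniform(-0.2, 0.2, 5)
        x = rng.standard_normal((n, d, d))
        labels = rng.integers(0, k, n)

        def loss():
            probs, _ = network_forward_cached(params, x)
            return float(-np.log(probs[np.arange(n), labels]).mean())

        probs, cache = network_forward_cached(params, x)
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1
        dlogits /= n
        g = network_backward(params, cache, dlogits)

        eps = 1e-6

        def fd(arr, idx):
            old = arr[idx]
            arr[idx] = old + eps
            lp = loss()
            arr[idx] = old - eps
            lm = loss()
            arr[idx] = old
            return (lp - lm) / (2 * eps)

        checks = []
        for layer in range(5):
            w = params.extractor.weights[layer]
            idx = tuple(int(rng.integers(0, s)) for s in w.shape)
            checks.append((g.conv_w[layer][idx], fd(w, idx)))
            b = params.extractor.biases[layer]
            i = int(rng.integers(0, b.size))
            checks.append((g.conv_b[layer][i], fd(b, (i,))))
            checks.append((g.ss_scales[layer], fd(params.ss.scales, (layer,))))
            checks.append((g.ss_shifts[layer], fd(params.ss.shifts, (layer,))))
        for arr, grad in (
            (params.classifier.w1, g.w1),
            (params.classifier.b1, g.b1),
            (params.classifier.w2, g.w2),
            (params.classifier.b2, g.b2),
        ):
            idx = tuple(int(rng.integers(0, s)) for s in arr.shape)
            checks.append((grad[idx], fd(arr, idx)))
        for analytic, numeric in checks:
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)
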