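import numpy as np
import pytest

from speckledemix.simulate import (
    EmitterMap,
    FrameStack,
    GroundTruth,
    OpticalConfig,
    compose_frames,
    generate_emitters,
    simulate_dataset,
    synthesize_fingerprints,
    synthesize_weights,
)


def brute_force_corr_peak(a: np.ndarray, b: np.ndarray):
    """Oracle: exhaustive zero-mean correlation over every circular lag."""
    a0 = a - a.mean()
    b0 = b - b.mean()
    norm = np.linalg.norm(a0) * np.linalg.norm(b0)
    best, best_lag = -np.inf, None
    H, W = a.shape
    for dr in range(H):
        for dc in range(W):
            v = float(np.sum(a0 * np.roll(b0, (dr, dc), axis=(0, 1)))) / norm
            if v > best:
                best, best_lag = v, (dr, dc)
    signed = tuple((l + n // 2) % n - n // 2 for l, n in zip(best_lag, a.shape))
    return signed, best


class TestOpticalConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            OpticalConfig(frame_height=4)
        with pytest.raises(ValueError):
            OpticalConfig(grain_size=0.5)
        with pytest.raises(ValueError):
            OpticalConfig(grain_size=5, me_range=4)
        with pytest.raises(ValueError):
            OpticalConfig(noise_photons=-1)


class TestGenerateEmitters:
    def test_single_emitter_deterministic(self):
        a = generate_emitters(1, fov_radius=10, seed=7)
        b = generate_emitters(1, fov_radius=10, seed=7)
        assert a.count == 1
        np.testing.assert_array_equal(a.positions, b.positions)
        assert np.hypot(*a.positions[0]) <= 10

    def test_min_separation_brute_force(self):
        em = generate_emitters(5, fov_radius=40, min_separation=10, seed=3)
        for i in range(5):
            for j in range(i + 1, 5):
                d = np.linalg.norm(em.positions[i] - em.positions[j])
                assert d >= 10

    def test_connected_chain_gaps(self):
        me_range = 14.0
        em = generate_emitters(
            7, fov_radius=40, layout="connected_chain", seed=2, chain_step=9.0
        )
        gaps = np.linalg.norm(np.diff(em.positions, axis=0), axis=1)
        assert gaps.max() < me_range

    def test_overdense_raises(self):
        with pytest.raises(RuntimeError):
            generate_emitters(50, fov_radius=5, min_separation=4, seed=0)

    def test_ring(self):
        em = generate_emitters(6, fov_radius=15, layout="ring", seed=1)
        radii = np.hypot(em.positions[:, 0], em.positions[:, 1])
        np.testing.assert_allclose(radii, 15.0)

    def test_bad_args(self):
        with pytest.raises(ValueError):
            generate_emitters(0, fov_radius=10)
        with pytest.raises(ValueError):
            generate_emitters(3, fov_radius=-1)
        with pytest.raises(ValueError):
            generate_emitters(3, fov_radius=10, layout="connected_chain")


class TestSynthesizeFingerprints:
    def test_identical_positions_identical_fingerprints(self, base_optics):
        em = EmitterMap(
            positions=np.array([[2.0, -3.0], [2.0, -3.0]]), brightness=np.ones(2)
        )
        W = synthesize_fingerprints(em, base_optics)
        np.testing.assert_array_equal(W[:, 0], W[:, 1])

    def test_shift_recovered_by_brute_force(self):
        cfg = OpticalConfig(
            frame_height=32, frame_width=32, grain_size=2.0, me_range=30.0, seed=9
        )
        em = EmitterMap(
            positions=np.array([[0.0, 0.0], [5.0, -3.0]]), brightness=np.ones(2)
        )
        W = synthesize_fingerprints(em, cfg)
        a = W[:, 0].reshape(32, 32)
        b = W[:, 1].reshape(32, 32)
        lag, peak = brute_force_corr_peak(a, b)
        # correlating emitter 0 against emitter 1 peaks at r_0 - r_1
        assert abs(lag[0] - (-5)) <= 1 and abs(lag[1] - 3) <= 1
        assert peak > 0.7

    def test_far_separation_decorrelates(self, pair_factory):
        peaks = []
        for seed in range(20):
            a, b = pair_factory(5 * 14.0, 0.0, seed=seed)
            a0, b0 = a - a.mean(), b - b.mean()
            corr = np.fft.ifft2(
                np.fft.fft2(a0) * np.conj(np.fft.fft2(b0))
            ).real / (np.linalg.norm(a0) * np.linalg.norm(b0))
            peaks.append(corr.max())
        assert np.mean(peaks) < 0.2

    def test_speckle_contrast(self, base_optics):
        em = generate_emitters(4, fov_radius=20, min_separation=5, seed=11)
        W = synthesize_fingerprints(em, base_optics)
        contrast = W.std(axis=0) / W.mean(axis=0)
        assert np.all(contrast >= 0.6) and np.all(contrast <= 1.1)

    def test_translation_property(self):
        # moving an emitter by an integer step moves its correlation peak
        # by exactly that step (within-memory-effect translation)
        for seed in range(10):
            cfg = OpticalConfig(
                frame_height=48, frame_width=48, grain_size=3.0, me_range=16.0,
                seed=seed,
            )
            rng = np.random.default_rng(seed)
            delta = rng.integers(1, 4, 2)
            base = np.array([1.0, -2.0])
            em = EmitterMap(
                positions=np.array([base, base + delta]), brightness=np.ones(2)
            )
            W = synthesize_fingerprints(em, cfg)
            a = W[:, 1].reshape(48, 48)
            b = W[:, 0].reshape(48, 48)
            a0, b0 = a - a.mean(), b - b.mean()
            corr = np.fft.ifft2(np.fft.fft2(a0) * np.conj(np.fft.fft2(b0))).real
            idx = np.unravel_index(np.argmax(corr), corr.shape)
            lag = tuple((l + n // 2) % n - n // 2 for l, n in zip(idx, corr.shape))
            assert lag == (int(delta[0]), int(delta[1]))

    def test_decorrelation_monotone_in_expectation(self):
        separations = [2.0, 8.0, 16.0, 32.0]
        means = []
        for d in separations:
            peaks = []
            for seed in range(50):
                cfg = OpticalConfig(
                    frame_height=48, frame_width=48, grain_size=3.0,
                    me_range=16.0, seed=1000 + seed,
                )
                em = EmitterMap(
                    positions=np.array([[0.0, 0.0], [d * 0.6, -d * 0.8]]),
                    brightness=np.ones(2),
                )
                W = synthesize_fingerprints(em, cfg)
                a = W[:, 0].reshape(48, 48)
                b = W[:, 1].reshape(48, 48)
                a0, b0 = a - a.mean(), b - b.mean()
                corr = np.fft.ifft2(
                    np.fft.fft2(a0) * np.conj(np.fft.fft2(b0))
                ).real / (np.linalg.norm(a0) * np.linalg.norm(b0))
                peaks.append(corr.max())
            means.append(np.mean(peaks))
        assert all(m1 >= m2 for m1, m2 in zip(means, means[1:]))


class TestSynthesizeWeights:
    def test_exponential_mean(self):
        h = synthesize_weights(1, 100, "iid_exponential", OpticalConfig(seed=5))
        # unit-mean exponential: SE = 1/sqrt(T)
        assert abs(h.mean() - 1.0) <= 3.0 / np.sqrt(100)

    def test_non_negative(self):
        for model in ("iid_exponential", "speckle_field"):
            em = EmitterMap(
                positions=np.array([[0.0, 0.0], [3.0, 1.0]]), brightness=np.ones(2)
            )
            h = synthesize_weights(
                2, 50, model, OpticalConfig(seed=1), emitters=em
            )
            assert h.min() >= 0

    def test_speckle_field_colocated_correlation(self, base_optics):
        em = EmitterMap(
            positions=np.array([[0.0, 0.0], [0.3, 0.0]]),  # 0.1 grain apart
            brightness=np.ones(2),
        )
        h = synthesize_weights(2, 500, "speckle_field", base_optics, emitters=em)
        r = np.corrcoef(h[0], h[1])[0, 1]
        assert r > 0.9

    def test_requires_emitters(self):
        with pytest.raises(ValueError):
            synthesize_weights(2, 10, "speckle_field", OpticalConfig())
        with pytest.raises(ValueError):
            synthesize_weights(0, 10)


class TestComposeFrames:
    def test_single_emitter_unit_weights(self, base_optics):
        em = EmitterMap(positions=np.array([[0.0, 0.0]]), brightness=np.ones(1))
        W = synthesize_fingerprints(em, base_optics)
        truth = GroundTruth(
            fingerprints=W, weights=np.ones((1, 5)), emitter_map=em,
            config=base_optics,
        )
        stack = compose_frames(truth)
        for t in range(5):
            np.testing.assert_array_equal(
                stack.frames[t], W[:, 0].reshape(base_optics.frame_shape)
            )

    def test_direct_sum_oracle(self, base_optics):
        em = generate_emitters(3, fov_radius=15, min_separation=5, seed=8)
        truth, stack = simulate_dataset(em, base_optics, 20)
        t = 13
        expected = np.zeros(base_optics.frame_shape)
        for k in range(3):
            expected += (
                truth.weights[k, t]
                * truth.fingerprints[:, k].reshape(base_optics.frame_shape)
            )
        np.testing.assert_allclose(stack.frames[t], expected, rtol=1e-12)

    def test_matrix_product_identity(self, base_optics):
        em = generate_emitters(4, fov_radius=15, min_separation=4, seed=2)
        truth, stack = simulate_dataset(em, base_optics, 30)
        product = (truth.fingerprints @ truth.weights).T.reshape(
            30, *base_optics.frame_shape
        )
        np.testing.assert_allclose(stack.frames, product, rtol=1e-12)

    def test_high_photon_limit(self, base_optics):
        em = generate_emitters(2, fov_radius=10, min_separation=4, seed=6)
        noiseless_truth, clean = simulate_dataset(em, base_optics, 10)
        noisy_cfg = OpticalConfig(
            frame_height=64, frame_width=64, grain_size=3.0, me_range=14.0,
            noise_photons=1e6, seed=0,
        )
        noisy_truth = GroundTruth(
            fingerprints=noiseless_truth.fingerprints,
            weights=noiseless_truth.weights,
            emitter_map=em,
            config=noisy_cfg,
        )
        noisy = compose_frames(noisy_truth)
        rel = np.abs(noisy.frames - clean.frames).sum() / clean.frames.sum()
        assert rel < 0.01

    def test_low_contrast_frames(self, base_optics):
        em = generate_emitters(12, fov_radius=25, min_separation=3, seed=10)
        truth, stack = simulate_dataset(em, base_optics, 40)
        fp_contrast = truth.fingerprints.std(axis=0) / truth.fingerprints.mean(axis=0)
        frame_contrast = (
            stack.frames.std(axis=(1, 2)) / stack.frames.mean(axis=(1, 2))
        )
        assert frame_contrast.mean() < fp_contrast.min()

    def test_shape_mismatch_raises(self, base_optics):
        em = EmitterMap(positions=np.array([[0.0, 0.0]]), brightness=np.ones(1))
        W = synthesize_fingerprints(em, base_optics)
        with pytest.raises(ValueError):
            GroundTruth(
                fingerprints=W[:-1], weights=np.ones((1, 5)), emitter_map=em,
                config=base_optics,
            )

    def test_frame_stack_validation(self):
        with pytest.raises(ValueError):
            FrameStack(frames=-np.ones((2, 8, 8)))
        with pytest.raises(ValueError):
            FrameStack(frames=np.ones((8, 8)))
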