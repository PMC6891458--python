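import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinatune.retina import (
    CHROMOSOME_BOUNDS,
    GENE_NAMES,
    ActivationSequence,
    Chromosome,
    SpikeRaster,
    SpikeTrain,
    Stage1Params,
    clip_chromosome,
    dog_filter,
    gaussian_kernel,
    log_filter,
    log_kernel,
    nlif_encode,
    random_chromosome,
    simulate_cell,
    stage1,
)
from retinatune.stimulus import FrameSequence, make_bar_stimulus


class TestGaussianKernel:
    @pytest.mark.parametrize("sigma,mu,k", [(0.5, 0.0, 3), (2.0, 0.5, 7), (1.3, -1.0, 9)])
    def test_sums_to_one(self, sigma, mu, k):
        assert gaussian_kernel(sigma, mu, k).sum() == pytest.approx(1.0, abs=1e-12)

    def test_rotation_symmetric_when_centred(self):
        k = gaussian_kernel(1.5, 0.0, 5)
        assert np.allclose(k, np.rot90(k))

    def test_flat_limit(self):
        # sigma >> k: every entry approaches 1/9
        k = gaussian_kernel(100.0, 0.0, 3)
        assert np.max(np.abs(k - 1.0 / 9.0)) < 1e-4

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(1.0, 0.0, 4)


class TestDogFilter:
    def test_constant_images_cancel(self):
        p = Stage1Params(sigma1=1.0, sigma2=2.0, k1=5, k2=5)
        img = np.full((11, 11), 0.37)
        out = dog_filter(img, img, p)
        assert np.max(np.abs(out)) < 1e-12

    def test_single_bright_pixel_centre_surround(self):
        p = Stage1Params(sigma1=0.8, sigma2=2.0, k1=7, k2=7)
        img = np.zeros((15, 15))
        img[7, 7] = 1.0
        out = dog_filter(img, img, p)
        assert out[7, 7] > 0  # centre excitation
        assert out[7, 10] < 0  # surround suppression

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 1, (2, 9, 9))
        p = Stage1Params()
        assert np.allclose(dog_filter(2 * a, 2 * b, p), 2 * dog_filter(a, b, p))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dog_filter(np.zeros((4, 4)), np.zeros((5, 5)), Stage1Params())


class TestLogFilter:
    def test_kernel_sums_to_zero(self):
        assert abs(log_kernel(1.0, 0.0, 7).sum()) < 1e-12

    def test_constant_image_zero(self):
        out = log_filter(np.full((9, 9), 0.8), Stage1Params(k1=5))
        assert np.max(np.abs(out)) < 1e-12

    def test_mexican_hat_signs(self):
        k = log_kernel(1.0, 0.0, 9)
        assert np.sign(k[4, 4]) != np.sign(k[0, 0])

    def test_linearity(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (9, 9))
        p = Stage1Params()
        assert np.allclose(log_filter(3 * img, p), 3 * log_filter(img, p))


class TestStage1:
    def test_all_black_gives_zeros(self):
        seq = FrameSequence(np.zeros((5, 8, 8)), 60.0, 26.0)
        act = stage1(seq, Stage1Params(), (4, 4))
        assert np.all(act.values == 0)

    def test_out_of_bounds_centre(self):
        seq = FrameSequence(np.zeros((2, 8, 8)), 60.0, 26.0)
        with pytest.raises(ValueError):
            stage1(seq, Stage1Params(), (8, 0))

    def test_toy_image_matches_brute_force_convolution(self):
        from scipy import ndimage

        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (1, 5, 5))
        seq = FrameSequence(img, 60.0, 26.0)
        p = Stage1Params(sigma1=0.5, sigma2=1.0, k1=3, k2=3, w1=1.0, w2=1.0, w3=1.0)
        value = stage1(seq, p, (2, 2)).values[0]

        kc = gaussian_kernel(0.5, 0.0, 3)
        ks = gaussian_kernel(1.0, 0.0, 3)
        kl = log_kernel(0.5, 0.0, 3)
        conv = lambda im, k: ndimage.convolve(im, k, mode="nearest")  # noqa: E731
        i0 = img[0]
        # grayscale: both DoG terms collapse onto DoG(I, I)
        expected = 2.0 * (conv(i0, kc) - conv(i0, ks))[2, 2] + conv(i0, kl)[2, 2]
        assert value == pytest.approx(expected, abs=1e-12)

    def test_grayscale_identity(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (3, 9, 9))
        seq = FrameSequence(img, 60.0, 26.0)
        p = Stage1Params(w1=0.2, w2=0.3, w3=0.5)
        act = stage1(seq, p, (4, 4))
        # S1 = (w1+w2)*dog(I, I) + w3*log(I) for grayscale input
        from scipy import ndimage

        kc = gaussian_kernel(p.sigma1, p.mu1, p.k1)
        ks = gaussian_kernel(p.sigma2, p.mu2, p.k2)
        kl = log_kernel(p.sigma1, p.mu1, p.k1)
        for t in range(3):
            dog = (
                ndimage.convolve(img[t], kc, mode="nearest")
                - ndimage.convolve(img[t], ks, mode="nearest")
            )[4, 4]
            log = ndimage.convolve(img[t], kl, mode="nearest")[4, 4]
            assert act.values[t] == pytest.approx(0.5 * dog + 0.5 * log, abs=1e-12)

    def test_linearity_in_stimulus(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 0.5, (4, 9, 9))
        p = Stage1Params()
        a1 = stage1(FrameSequence(img, 60.0, 26.0), p, (4, 4)).values
        a2 = stage1(FrameSequence(2 * img, 60.0, 26.0), p, (4, 4)).values
        assert np.allclose(a2, 2 * a1)


def _chromosome(**overrides) -> Chromosome:
    base = dict(
        K=7, leakage=12.0, threshold=250.0, persistence_time=5,
        refractory_period=3.0, fmf=0.3,
    )
    base.update(overrides)
    return Chromosome(**base)


class TestNlifEncode:
    def test_zero_input_no_noise_no_spikes(self):
        act = ActivationSequence(np.zeros(60), 60.0)
        train = nlif_encode(act, _chromosome(), noise_sd=0.0)
        assert train.n_spikes == 0

    def test_refractory_contract(self):
        rng = np.random.default_rng(0)
        act = ActivationSequence(rng.uniform(0, 0.2, 120), 60.0)
        c = _chromosome(refractory_period=8.0)
        train = nlif_encode(act, c, input_gain=400.0, noise_sd=30.0, seed=5)
        if train.n_spikes >= 2:
            assert np.min(np.diff(train.spike_times_ms)) >= c.refractory_period

    def test_constant_drive_matches_recurrence_oracle(self):
        c = _chromosome(fmf=0.25, persistence_time=4)
        value = 0.1
        gain = 300.0
        act = ActivationSequence(np.full(120, value), 60.0)
        train = nlif_encode(act, c, input_gain=gain, noise_sd=0.0)
        assert train.n_spikes >= 3

        # independent oracle: iterate the published recurrence step by step
        pt = c.persistence_time
        dt = (1000.0 / 60.0) / pt
        spikes = []
        v = 0.0
        release = 0.0
        for i in range(120 * pt):
            frame = i // pt
            s_now = value
            s_prev = value if frame > 0 else 0.0
            drive = (1 - c.fmf) * s_now + c.fmf * pt * (s_now - s_prev)
            t_end = (i + 1) * dt
            if t_end <= release:
                continue
            v = v - v * dt / c.leakage + gain * drive * dt
            if v >= c.threshold:
                spikes.append(t_end)
                v = 0.0
                release = t_end + c.refractory_period
        spikes = [t for t in spikes if t < 2000.0]
        assert np.allclose(train.spike_times_ms, spikes)

    def test_seed_reproducibility(self):
        act = ActivationSequence(np.full(60, 0.05), 60.0)
        a = nlif_encode(act, _chromosome(), noise_sd=20.0, seed=42)
        b = nlif_encode(act, _chromosome(), noise_sd=20.0, seed=42)
        assert np.array_equal(a.spike_times_ms, b.spike_times_ms)

    def test_threshold_monotonicity_noise_free(self):
        rng = np.random.default_rng(2)
        act = ActivationSequence(rng.uniform(0, 0.15, 180), 60.0)
        counts = []
        for thr in (225.0, 240.0, 255.0, 275.0):
            counts.append(nlif_encode(act, _chromosome(threshold=thr),
                                      input_gain=500.0, noise_sd=0.0).n_spikes)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_spikes_within_duration(self, seed):
        act = ActivationSequence(np.full(30, 0.08), 60.0)
        train = nlif_encode(act, _chromosome(), input_gain=500.0, noise_sd=40.0, seed=seed)
        assert np.all(train.spike_times_ms >= 0)
        assert np.all(train.spike_times_ms < train.duration_ms)
        if train.n_spikes >= 2:
            assert np.min(np.diff(train.spike_times_ms)) >= _chromosome().refractory_period


@pytest.fixture(scope="module")
def stim():
    return make_bar_stimulus(24, 32, direction_deg=0)


class TestSimulateCell:
    def test_trial_count_and_duration(self, stim):
        raster = simulate_cell(_chromosome(), Stage1Params(), stim, n_trials=4, noise_sd=10.0)
        assert raster.n_trials == 4
        assert len({t.duration_ms for t in raster.trials}) == 1

    def test_noise_free_trials_identical(self, stim):
        raster = simulate_cell(_chromosome(), Stage1Params(), stim, n_trials=3, noise_sd=0.0)
        for t in raster.trials[1:]:
            assert np.array_equal(t.spike_times_ms, raster.trials[0].spike_times_ms)

    def test_same_seed_identical(self, stim):
        a = simulate_cell(_chromosome(), Stage1Params(), stim, n_trials=2, noise_sd=15.0, seed=9)
        b = simulate_cell(_chromosome(), Stage1Params(), stim, n_trials=2, noise_sd=15.0, seed=9)
        for ta, tb in zip(a.trials, b.trials):
            assert np.array_equal(ta.spike_times_ms, tb.spike_times_ms)


class TestChromosome:
    def test_random_within_bounds(self, rng):
        for _ in range(1000):
            c = random_chromosome(rng)
            for g in GENE_NAMES:
                lo, hi = CHROMOSOME_BOUNDS[g]
                assert lo <= getattr(c, g) <= hi
            assert isinstance(c.K, int)
            assert isinstance(c.persistence_time, int)

    def test_clip_k(self):
        c = clip_chromosome([20, 12.0, 250.0, 5, 4.0, 0.3])
        assert c.K == 13

    def test_clip_fmf(self):
        c = clip_chromosome([7, 12.0, 250.0, 5, 4.0, 0.1])
        assert c.fmf == 0.25

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            _chromosome(threshold=300.0)

    def test_round_trip_array(self):
        c = _chromosome()
        assert Chromosome.from_array(c.to_array()) == c


class TestSpikeContainers:
    def test_spike_train_ordering_enforced(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([5.0, 4.0]), 10.0)

    def test_spike_train_duration_enforced(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([5.0, 12.0]), 10.0)

    def test_raster_requires_shared_duration(self):
        a = SpikeTrain(np.array([1.0]), 10.0)
        b = SpikeTrain(np.array([1.0]), 20.0)
        with pytest.raises(ValueError):
            SpikeRaster((a, b))

    def test_raster_requires_trials(self):
        with pytest.raises(ValueError):
            SpikeRaster(())
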