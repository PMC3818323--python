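"""Stimulus generators: distributional oracles and reproducibility."""

import numpy as np
import pytest
from scipy import stats

from psdlearn import RngSpec
from psdlearn.datagen import (ImageSpec, PatternSpec, digit_templates,
                              generate_pattern, jitter_pattern,
                              make_category_set, make_digit_images)


class TestGeneratePattern:
    def test_single_uniform_counts(self):
        spec = PatternSpec(n_afferents=500, window=200.0,
                           rng=RngSpec(1, "g"))
        pat = generate_pattern(spec)
        assert pat.n_afferents == 500
        assert pat.n_spikes == 500
        assert all(len(tr) == 1 for tr in pat.trains)

    def test_single_uniform_times_are_uniform(self):
        """Pooled spike times pass a KS uniformity check at alpha = 0.01."""
        spec = PatternSpec(n_afferents=1000, window=200.0, rng=RngSpec(2, "g"))
        times = np.concatenate([generate_pattern(spec, np.random.default_rng(s)
                                                 ).flat()[1] for s in range(5)])
        p = stats.kstest(times / 200.0, "uniform").pvalue
        assert p > 0.01

    def test_poisson_total_count_within_3_sigma(self):
        """Expected spikes = N * r * T / 1000 for a fixed-rate Poisson pattern."""
        rate, n, window = 20.0, 200, 200.0
        spec = PatternSpec(n_afferents=n, window=window, mode="poisson",
                           rate_range=(rate, rate))
        counts = [generate_pattern(spec, np.random.default_rng(s)).n_spikes
                  for s in range(100)]
        expect = n * rate * window / 1000.0
        sd = np.sqrt(expect)  # Poisson variance per pattern
        assert abs(np.mean(counts) - expect) < 3 * sd / np.sqrt(len(counts))

    def test_zero_window_degenerate(self):
        spec = PatternSpec(n_afferents=10, window=0.0)
        assert generate_pattern(spec).n_spikes == 0

    def test_reproducible_under_fixed_rng(self):
        spec = PatternSpec(n_afferents=50, window=100.0, rng=RngSpec(9, "r"))
        a, b = generate_pattern(spec), generate_pattern(spec)
        np.testing.assert_array_equal(a.flat()[1], b.flat()[1])


class TestJitter:
    def test_sigma_zero_identity(self, rng):
        spec = PatternSpec(n_afferents=50, window=100.0)
        pat = generate_pattern(spec, rng.generator())
        assert jitter_pattern(pat, 0.0, rng) is pat

    def test_spike_count_conserved(self, rng):
        spec = PatternSpec(n_afferents=100, window=100.0, mode="poisson")
        pat = generate_pattern(spec, rng.generator())
        jit = jitter_pattern(pat, 5.0, rng)
        assert jit.n_spikes == pat.n_spikes

    def test_empirical_sd_matches_sigma_for_interior_spikes(self):
        """Moment check on 10^4 interior spikes, 3-sigma band."""
        sigma, window = 2.0, 200.0
        gen = np.random.default_rng(0)
        base_t = gen.uniform(50.0, 150.0, size=10_000)  # away from boundaries
        from psdlearn.spike_core import SpikePattern, SpikeTrain
        pat = SpikePattern([SpikeTrain([t], window) for t in base_t], window)
        jit = jitter_pattern(pat, sigma, RngSpec(3, "j"))
        deltas = jit.flat()[1] - pat.flat()[1]
        se_sd = sigma / np.sqrt(2 * deltas.size)
        assert abs(deltas.std() - sigma) < 3 * se_sd
        assert abs(deltas.mean()) < 3 * sigma / np.sqrt(deltas.size)

    def test_reflection_keeps_times_in_window(self, rng):
        spec = PatternSpec(n_afferents=200, window=10.0)
        pat = generate_pattern(spec, rng.generator())
        jit = jitter_pattern(pat, 8.0, rng)  # jitter comparable to window
        t = jit.flat()[1]
        assert t.min() >= 0.0 and t.max() <= 10.0


class TestCategorySet:
    def test_shapes_and_labels(self, rng):
        spec = PatternSpec(n_afferents=30, window=100.0)
        templates, inst = make_category_set(3, 20, spec, 2.0, rng)
        assert len(templates) == 3
        assert len(inst) == 60
        labels = [c for _, c in inst]
        assert labels.count(0) == labels.count(1) == labels.count(2) == 20

    def test_sigma_zero_instances_equal_template(self, rng):
        spec = PatternSpec(n_afferents=20, window=100.0)
        templates, inst = make_category_set(2, 3, spec, 0.0, rng)
        for pat, c in inst:
            np.testing.assert_array_equal(pat.flat()[1],
                                          templates[c].flat()[1])


class TestDigits:
    def test_templates_are_binary_20x20(self):
        tpls = digit_templates()
        assert len(tpls) == 10
        for t in tpls:
            assert t.pixels.shape == (20, 20)
            assert set(np.unique(t.pixels)) <= {0, 1}
        # all ten digits are distinct bitmaps
        flat = {t.pixels.tobytes() for t in tpls}
        assert len(flat) == 10

    def test_noise_zero_exact_templates(self):
        images = make_digit_images(0.0, 2, RngSpec(1, "d"))
        tpls = {t.label: t.pixels for t in digit_templates()}
        for img in images:
            np.testing.assert_array_equal(img.pixels, tpls[img.label])

    def test_noise_one_exact_complement(self):
        images = make_digit_images(1.0, 1, RngSpec(1, "d"))
        tpls = {t.label: t.pixels for t in digit_templates()}
        for img in images:
            np.testing.assert_array_equal(img.pixels, 1 - tpls[img.label])

    def test_flip_count_matches_binomial(self):
        """Expected flips = 400 * noise, 3-sigma band over 100 images."""
        noise = 0.1
        images = make_digit_images(noise, 10, RngSpec(5, "d"))
        tpls = {t.label: t.pixels for t in digit_templates()}
        flips = np.array([(img.pixels != tpls[img.label]).sum()
                          for img in images])
        expect = 400 * noise
        sd = np.sqrt(400 * noise * (1 - noise))
        assert abs(flips.mean() - expect) < 3 * sd / np.sqrt(flips.size)

    def test_non_binary_image_rejected(self):
        with pytest.raises(ValueError):
            ImageSpec(np.array([[0, 2]]), "x")

    def test_invalid_noise_level_rejected(self):
        with pytest.raises(ValueError):
            make_digit_images(1.5, 1, RngSpec(0, "d"))
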