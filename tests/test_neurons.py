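"""Neuron simulators: LIF against closed forms, Izhikevich characterization."""

import numpy as np
import pytest

from psdlearn import (IMParams, KernelParams, LIFParams, NoiseSpec, RngSpec,
                      SpikePattern, SpikeTrain, SynapticState, kernel_value,
                      simulate_izhikevich, simulate_lif, synaptic_current)


def constant_pattern(window: float, n: int = 1) -> SpikePattern:
    return SpikePattern([SpikeTrain([], window)] * n, window)


class TestSynapticCurrent:
    def test_zero_weights_zero_current(self, small_pattern, kernel):
        t = np.linspace(0, 100, 50)
        assert np.all(synaptic_current(small_pattern, np.zeros(3), kernel, t) == 0)

    def test_single_afferent_matches_kernel(self, kernel):
        pat = SpikePattern([SpikeTrain([10.0], 100.0)], 100.0)
        w = 0.7
        for t in (12.0, 20.0, 50.0):
            assert synaptic_current(pat, [w], kernel, t) == pytest.approx(
                w * kernel_value(t - 10.0, kernel), abs=1e-12)

    def test_homogeneity(self, small_pattern, kernel, rng):
        w = rng.generator().uniform(size=3)
        t = np.linspace(0, 100, 20)
        np.testing.assert_allclose(
            synaptic_current(small_pattern, 2 * w, kernel, t),
            2 * synaptic_current(small_pattern, w, kernel, t), rtol=1e-12)

    def test_length_mismatch_rejected(self, small_pattern, kernel):
        with pytest.raises(ValueError):
            synaptic_current(small_pattern, np.zeros(2), kernel, 0.0)


class TestLIF:
    def test_silent_without_input(self, lif, kernel):
        pat = constant_pattern(200.0)
        u, out = simulate_lif(pat, SynapticState(np.zeros(1), 0.5), lif, kernel)
        assert len(out) == 0
        np.testing.assert_array_equal(u, lif.v_rest)

    def test_constant_current_isi_matches_closed_form(self, lif, kernel):
        """ISI = t_ref + tau_m * ln(RI / (RI - theta)) under constant drive."""
        current = 1.5
        dt = 0.01
        window = 500.0
        pat = constant_pattern(window)
        _, out = simulate_lif(pat, SynapticState(np.zeros(1), 0.5), lif, kernel,
                              dt=dt, _noise_arr=np.full(int(window / dt), current))
        isi = np.diff(out.times)
        predicted = lif.t_ref + lif.tau_m * np.log(
            lif.r_m * current / (lif.r_m * current - lif.theta))
        assert isi == pytest.approx(predicted, abs=2 * dt)

    def test_refractory_invariant(self, lif, kernel, rng):
        gen = rng.generator()
        trains = [SpikeTrain(np.unique(gen.uniform(0, 200.0, size=3)), 200.0)
                  for _ in range(100)]
        pat = SpikePattern(trains, 200.0)
        syn = SynapticState(np.full(100, 0.3), 0.5)
        _, out = simulate_lif(pat, syn, lif, kernel)
        assert len(out) > 1
        assert np.all(np.diff(out.times) >= lif.t_ref - 1e-9)

    def test_deterministic_without_noise(self, lif, kernel, rng):
        gen = rng.generator()
        trains = [SpikeTrain([gen.uniform(0, 200.0)], 200.0) for _ in range(50)]
        pat = SpikePattern(trains, 200.0)
        syn = SynapticState(np.full(50, 0.2), 0.5)
        _, out1 = simulate_lif(pat, syn, lif, kernel)
        _, out2 = simulate_lif(pat, syn, lif, kernel)
        np.testing.assert_array_equal(out1.times, out2.times)

    def test_grid_refinement_moves_spikes_less_than_dt(self, lif, kernel, rng):
        gen = rng.generator()
        trains = [SpikeTrain([gen.uniform(0, 150.0)], 200.0) for _ in range(80)]
        pat = SpikePattern(trains, 200.0)
        syn = SynapticState(np.full(80, 0.15), 0.5)
        _, coarse = simulate_lif(pat, syn, lif, kernel, dt=0.1)
        _, fine = simulate_lif(pat, syn, lif, kernel, dt=0.05)
        assert len(coarse) == len(fine)
        assert np.max(np.abs(coarse.times - fine.times)) <= 0.1 + 1e-9

    def test_spike_count_monotone_in_weight(self, lif, kernel, rng):
        gen = rng.generator()
        trains = [SpikeTrain([gen.uniform(0, 180.0)], 200.0) for _ in range(60)]
        pat = SpikePattern(trains, 200.0)
        counts = []
        for scale in (0.05, 0.1, 0.2, 0.3):
            syn = SynapticState(np.full(60, scale), 0.5)
            _, out = simulate_lif(pat, syn, lif, kernel)
            counts.append(len(out))
        assert counts == sorted(counts)

    def test_noise_reproducible_by_rng_spec(self, lif, kernel):
        pat = constant_pattern(100.0)
        syn = SynapticState(np.zeros(1), 0.5)
        noise = NoiseSpec(current_sd=2.0, rng=RngSpec(7, "bg"))
        _, a = simulate_lif(pat, syn, lif, kernel, noise)
        _, b = simulate_lif(pat, syn, lif, kernel, noise)
        np.testing.assert_array_equal(a.times, b.times)

    def test_coarse_dt_rejected(self, lif, kernel):
        with pytest.raises(ValueError):
            simulate_lif(constant_pattern(10.0), SynapticState(np.zeros(1), 0.5),
                         lif, kernel, dt=5.0)


class TestIzhikevich:
    def test_settles_at_rest_without_input(self, kernel):
        im = IMParams()
        pat = constant_pattern(300.0, 5)
        v, out = simulate_izhikevich(pat, SynapticState(np.zeros(5), 0.5), im,
                                     kernel)
        assert len(out) == 0
        assert v[-1] == pytest.approx(im.v_rest, abs=0.1)

    def test_regular_spiking_under_sustained_drive(self, kernel):
        """Staggered periodic afferents give near-constant drive; ISI CV < 0.05."""
        window = 600.0
        trains = [SpikeTrain(np.arange(i, window - 1e-9, 40.0), window)
                  for i in range(40)]
        pat = SpikePattern(trains, window)
        syn = SynapticState(np.full(40, 0.08), 0.5)
        _, out = simulate_izhikevich(pat, syn, IMParams(), kernel)
        isi = np.diff(out.times)[3:]  # drop onset transient
        assert isi.size > 5
        assert isi.std() / isi.mean() < 0.05

    def test_refractory_like_minimum_isi(self, kernel, rng):
        """Recovery dynamics keep consecutive spikes a few ms apart."""
        gen = rng.generator()
        trains = [SpikeTrain(np.unique(gen.uniform(0, 200.0, size=4)), 200.0)
                  for _ in range(100)]
        pat = SpikePattern(trains, 200.0)
        syn = SynapticState(np.full(100, 0.3), 0.5)
        _, out = simulate_izhikevich(pat, syn, IMParams(), kernel)
        if len(out) > 1:
            assert np.min(np.diff(out.times)) >= 1.0 - 1e-9
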