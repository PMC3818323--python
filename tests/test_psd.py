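"""The plasticity rule: sign structure, event-sum oracle, training dynamics."""

import numpy as np
import pytest

from psdlearn import (KernelParams, LIFParams, PSDConfig, RngSpec,
                      SpikePattern, SpikeTrain, SynapticState, apply_update,
                      initial_weights, psc_trace, psd_delta, train_one_pattern,
                      train_pattern_set, van_rossum_distance)
from psdlearn.datagen import PatternSpec, generate_pattern
from psdlearn.experiments import default_target
from tests.conftest import random_train


def delta_event_sum_oracle(pattern, desired, actual, kernel, eta):
    """Independent reference: explicit loop over spike events and afferents."""
    dw = np.zeros(pattern.n_afferents)
    for i, tr in enumerate(pattern.trains):
        for t_d in desired.times:
            dw[i] += eta * psc_trace(tr, kernel, t_d)
        for t_o in actual.times:
            dw[i] -= eta * psc_trace(tr, kernel, t_o)
    return dw


class TestPsdDelta:
    def test_equals_event_sum_oracle(self, kernel, rng):
        gen = rng.generator()
        for _ in range(10):
            pat = SpikePattern([random_train(gen) for _ in range(8)], 100.0)
            desired, actual = random_train(gen), random_train(gen)
            got = psd_delta(pat, desired, actual, kernel, eta=0.05)
            want = delta_event_sum_oracle(pat, desired, actual, kernel, 0.05)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_no_change_when_actual_equals_desired(self, kernel, rng):
        gen = rng.generator()
        pat = SpikePattern([random_train(gen) for _ in range(10)], 100.0)
        tr = SpikeTrain([20.0, 60.0], 100.0)
        np.testing.assert_array_equal(psd_delta(pat, tr, tr, kernel, 0.1),
                                      np.zeros(10))

    def test_miss_potentiates(self, kernel):
        """Desired spike with silent output: afferents firing before it gain weight."""
        pat = SpikePattern([SpikeTrain([35.0], 100.0)], 100.0)
        dw = psd_delta(pat, SpikeTrain([40.0], 100.0), SpikeTrain([], 100.0),
                       kernel, eta=0.1)
        assert dw[0] == pytest.approx(0.1 * psc_trace(pat.trains[0], kernel, 40.0))
        assert dw[0] > 0

    def test_false_alarm_depresses(self, kernel, rng):
        gen = rng.generator()
        pat = SpikePattern([random_train(gen, max_spikes=3) for _ in range(20)],
                           100.0)
        dw = psd_delta(pat, SpikeTrain([], 100.0), SpikeTrain([50.0], 100.0),
                       kernel, eta=0.1)
        assert np.all(dw <= 0)

    def test_acausal_afferent_unchanged(self, kernel):
        """An afferent spiking after every output event has zero eligibility."""
        pat = SpikePattern([SpikeTrain([90.0], 100.0)], 100.0)
        dw = psd_delta(pat, SpikeTrain([40.0], 100.0), SpikeTrain([60.0], 100.0),
                       kernel, eta=0.1)
        assert dw[0] == 0.0

    def test_sign_rules_exact(self, kernel, rng):
        gen = rng.generator()
        for _ in range(10):
            pat = SpikePattern([random_train(gen) for _ in range(15)], 100.0)
            ev = random_train(gen, max_spikes=4)
            empty = SpikeTrain([], 100.0)
            assert np.all(psd_delta(pat, ev, empty, kernel, 0.1) >= 0)
            assert np.all(psd_delta(pat, empty, ev, kernel, 0.1) <= 0)

    def test_window_mismatch_rejected(self, kernel, small_pattern):
        with pytest.raises(ValueError):
            psd_delta(small_pattern, SpikeTrain([], 50.0), SpikeTrain([], 100.0),
                      kernel, 0.1)


class TestApplyUpdate:
    def test_zero_delta_identity(self):
        syn = SynapticState(np.array([0.1, 0.2]), 0.5)
        out = apply_update(syn, np.zeros(2))
        np.testing.assert_array_equal(out.weights, syn.weights)

    def test_upper_cap_enforced(self):
        syn = SynapticState(np.array([0.45]), 0.5)
        out = apply_update(syn, np.array([0.2]))
        assert out.weights[0] == 0.5

    def test_no_lower_clip(self):
        syn = SynapticState(np.array([0.1]), 0.5)
        out = apply_update(syn, np.array([-0.4]))
        assert out.weights[0] == pytest.approx(-0.3)


class TestTraining:
    def test_converges_and_is_fixed_point(self, lif):
        """After convergence a no-learning rerun reproduces the target."""
        cfg = PSDConfig()
        rng = RngSpec(3, "fp")
        gen = rng.generator()
        spec = PatternSpec(n_afferents=500, window=200.0)
        pat = generate_pattern(spec, gen)
        target = default_target(200.0)
        syn = initial_weights(500, 200.0, cfg.kernel, lif, cfg.w_max,
                              rng.child("w"))
        rec = train_one_pattern(pat, target, syn, lif, cfg, rng.child("t"))
        assert rec.converged_epoch is not None
        from psdlearn import simulate_lif
        syn2 = SynapticState(rec.weights_final, cfg.w_max)
        _, out = simulate_lif(pat, syn2, lif, cfg.kernel)
        assert van_rossum_distance(out, target, cfg.metric) < \
            cfg.convergence_distance

    def test_online_mode_converges(self, lif):
        cfg = PSDConfig(update_mode="online")
        rng = RngSpec(5, "online")
        gen = rng.generator()
        pat = generate_pattern(PatternSpec(n_afferents=300, window=200.0), gen)
        syn = initial_weights(300, 200.0, cfg.kernel, lif, cfg.w_max,
                              rng.child("w"))
        rec = train_one_pattern(pat, default_target(200.0), syn, lif, cfg,
                                rng.child("t"))
        assert rec.converged_epoch is not None

    def test_retarget_reconverges(self):
        from psdlearn.experiments import run_retarget
        first, second = run_retarget(seed=2)
        assert first.converged_epoch is not None
        assert second.converged_epoch is not None

    def test_single_pattern_set_reduces_to_one_pattern(self, lif):
        cfg = PSDConfig(max_epochs=50)
        rng = RngSpec(11, "red")
        gen = rng.generator()
        pat = generate_pattern(PatternSpec(n_afferents=400, window=200.0), gen)
        target = default_target(200.0)
        syn = initial_weights(400, 200.0, cfg.kernel, lif, cfg.w_max,
                              rng.child("w"))
        r1 = train_one_pattern(pat, target, syn.copy(), lif, cfg, rng.child("t"))
        r2 = train_pattern_set([pat], [target], syn.copy(), lif, cfg,
                               rng.child("t"))
        assert r1.converged_epoch == r2.converged_epoch
        np.testing.assert_array_equal(r1.weights_final, r2.weights_final)

    def test_overload_fails_at_max_epochs(self, lif):
        """Load far above capacity never memorizes within the budget."""
        from psdlearn.experiments import category_target
        cfg = PSDConfig(max_epochs=30)
        rng = RngSpec(13, "over")
        gen = rng.generator()
        n, p = 100, 60  # load 0.6 >> capacity
        pats = [generate_pattern(PatternSpec(n_afferents=n, window=200.0), gen)
                for _ in range(p)]
        desired = [category_target(i % 4, 4, 200.0) for i in range(p)]
        syn = initial_weights(n, 200.0, cfg.kernel, lif, cfg.w_max,
                              rng.child("w"))
        rec = train_pattern_set(pats, desired, syn, lif, cfg, rng.child("t"))
        assert rec.converged_epoch is None
        assert rec.n_epochs == 30

    def test_record_invariants(self):
        from psdlearn.experiments import run_association
        rec = run_association(seed=4, record_weights=True)
        assert rec.n_epochs <= PSDConfig().max_epochs
        assert rec.converged_epoch == rec.n_epochs
        assert rec.distance_per_epoch[rec.converged_epoch - 1] < \
            PSDConfig().convergence_distance
        assert len(rec.weights_per_epoch) == rec.n_epochs


class TestWeightStructure:
    def test_causal_connectivity_after_training(self, lif):
        """Afferents spiking shortly before target times end up with larger weights."""
        from psdlearn.experiments import run_association
        cfg = PSDConfig()
        target = default_target(200.0)
        diffs = []
        for seed in range(30):
            rng = RngSpec(seed, "causal")
            gen = rng.generator()
            pat = generate_pattern(PatternSpec(n_afferents=500, window=200.0),
                                   gen)
            syn = initial_weights(500, 200.0, cfg.kernel, lif, cfg.w_max,
                                  rng.child("w"))
            rec = train_one_pattern(pat, target, syn, lif, cfg, rng.child("t"))
            spike_t = np.array([tr.times[0] for tr in pat.trains])
            causal = np.zeros(500, dtype=bool)
            for td in target.times:
                causal |= (spike_t >= td - 2 * cfg.kernel.tau_s) & (spike_t <= td)
            w = rec.weights_final
            diffs.append(w[causal].mean() - w[~causal].mean())
        diffs = np.asarray(diffs)
        # overwhelmingly positive across runs
        assert (diffs > 0).mean() > 0.9
        assert diffs.mean() > 0

    def test_smaller_tau_s_concentrates_weights_near_targets(self, lif):
        """A narrower kernel leaves the positive weight mass concentrated on
        the few afferents spiking just before the target times; a wider one
        spreads it.  Paired over 20 seeds (same pattern and initial weights
        per seed for both kernels)."""
        base = KernelParams()
        target = default_target(200.0)
        frac = {}
        for tau_s in (base.tau_s / 2, 2 * base.tau_s):
            cfg = PSDConfig(kernel=KernelParams.from_ratio(tau_s=tau_s))
            vals = []
            for seed in range(40):
                rng = RngSpec(seed, "conc")
                gen = rng.generator()
                pat = generate_pattern(
                    PatternSpec(n_afferents=500, window=200.0), gen)
                syn = initial_weights(500, 200.0, base, lif, cfg.w_max,
                                      rng.child("w"))
                rec = train_one_pattern(pat, target, syn, lif, cfg,
                                        rng.child("t"))
                w = np.clip(rec.weights_final, 0, None)
                spike_t = np.array([tr.times[0] for tr in pat.trains])
                near = np.zeros(500, dtype=bool)
                for td in target.times:
                    near |= (spike_t >= td - 5.0) & (spike_t <= td)
                vals.append(w[near].sum() / w.sum())
            frac[tau_s] = np.asarray(vals)
        diff = frac[base.tau_s / 2] - frac[2 * base.tau_s]
        from scipy import stats
        assert diff.mean() > 0
        assert stats.ttest_1samp(diff, 0.0, alternative="greater").pvalue < 0.05
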