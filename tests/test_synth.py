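"""Generator behaviour: SR profile, noise mapping, phase reset, coupling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import srsync as ss
from srsync.spectral import intertrial_coherence


class TestSRProfile:
    def test_zero_noise_gives_baseline(self):
        p = ss.SRProfileParams(0.7, 2.0, 1.5)
        assert ss.sr_profile(0.0, p) == pytest.approx(0.7)

    def test_peak_at_sigma_opt(self):
        p = ss.SRProfileParams(0.5, 3.0, 2.0)
        assert ss.sr_profile(2.0, p) == pytest.approx(3.5)

    def test_value_at_twice_sigma_opt(self):
        # 4 * exp(-3), evaluated directly from the profile formula
        p = ss.SRProfileParams(0.0, 1.0, 1.0)
        assert ss.sr_profile(2.0, p) == pytest.approx(4.0 * math.exp(-3.0), rel=1e-12)
        assert ss.sr_profile(2.0, p) == pytest.approx(0.19915, abs=5e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ss.InvalidConfigError):
            ss.sr_profile(-0.1, ss.SRProfileParams(0.0, 1.0, 1.0))

    def test_invalid_params_rejected(self):
        with pytest.raises(ss.InvalidConfigError):
            ss.SRProfileParams(0.0, 1.0, 0.0)
        with pytest.raises(ss.InvalidConfigError):
            ss.SRProfileParams(-0.1, 1.0, 1.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        sigma=st.floats(0.0, 50.0),
        kappa0=st.floats(0.0, 5.0),
        kappa_sr=st.floats(0.0, 10.0),
        sigma_opt=st.floats(0.1, 10.0),
    )
    def test_profile_bounded_and_peaked(self, sigma, kappa0, kappa_sr, sigma_opt):
        p = ss.SRProfileParams(kappa0, kappa_sr, sigma_opt)
        k = ss.sr_profile(sigma, p)
        assert kappa0 <= k <= kappa0 + kappa_sr + 1e-12
        assert ss.sr_profile(sigma_opt, p) == pytest.approx(kappa0 + kappa_sr)


class TestNoiseAmplitude:
    @pytest.mark.parametrize(
        "label,scale,expected",
        [("none", 2.5, 0.0), ("0", 1.0, 1.0), ("20", 1.0, 10.0),
         ("-5", 2.0, 2.0 * 10 ** (-0.25)), ("10", 0.5, 0.5 * 10**0.5)],
    )
    def test_db_mapping(self, label, scale, expected):
        assert ss.noise_amplitude(label, scale) == pytest.approx(expected)

    def test_unknown_label(self):
        with pytest.raises(KeyError):
            ss.noise_amplitude("loud", 1.0)


class TestConfigValidation:
    def test_duplicate_conditions_rejected(self):
        with pytest.raises(ss.InvalidConfigError):
            ss.default_config(conditions=("none", "0", "0"))

    def test_missing_zero_label_rejected(self):
        with pytest.raises(ss.InvalidConfigError):
            ss.default_config(conditions=("-5", "0", "5"))

    def test_epoch_window_must_contain_baseline(self):
        with pytest.raises(ss.InvalidConfigError):
            ss.default_config(epoch_window=(-0.05, 0.45))

    def test_contradictory_coupling_rejected(self):
        specs = (
            ss.CouplingSpec(("A", "B"), (9.0, 14.0), (0.0, 0.2), ss.SRProfileParams(0, 1, 1)),
            ss.CouplingSpec(("B", "C"), (10.0, 13.0), (0.1, 0.3), ss.SRProfileParams(0, 1, 1)),
        )
        with pytest.raises(ss.InvalidConfigError):
            ss.default_config(sources=("A", "B", "C"), coupling=specs,
                              reset_params={s: ss.SRProfileParams(0.2, 2.5, 1.0)
                                            for s in ("A", "B", "C")})


class TestSourceEpochs:
    def test_reproducible_under_seed(self):
        cfg = ss.default_config(n_trials=10)
        a = ss.generate_source_epochs(cfg, "S", "R_STG", "5", np.random.default_rng(42))
        b = ss.generate_source_epochs(cfg, "S", "R_STG", "5", np.random.default_rng(42))
        np.testing.assert_array_equal(a.data, b.data)

    def test_no_oscillation_means_flat_ersp(self, default_grid):
        cfg = ss.default_config(n_trials=200, a_osc=0.0)
        ep = ss.generate_source_epochs(cfg, "S", "R_STG", "0", np.random.default_rng(3))
        emap = ss.ersp(ss.morlet_tf(ep, default_grid))
        win = ss.WindowSpec(0.0, 0.1, 30.0, 50.0)
        from srsync.windows import pixel_mask
        sel = pixel_mask(emap.freqs, emap.times, win, emap.valid_mask)
        assert abs(emap.ersp[sel].mean()) < 0.3

    def test_near_deterministic_reset_gives_full_phase_locking(self, default_grid):
        cfg = ss.default_config(
            n_trials=80,
            reset_params={s: ss.SRProfileParams(1e6, 0.0, 1.0) for s in ss.synth.DEFAULT_SOURCES},
        )
        ep = ss.generate_source_epochs(cfg, "S", "R_STG", "none", np.random.default_rng(4))
        tf = ss.morlet_tf(ep, default_grid)
        itc = intertrial_coherence(tf)
        fi = np.argmin(np.abs(default_grid.freqs - 40.0))
        sel = (tf.times >= 0.010) & (tf.times <= 0.100) & tf.valid_mask[fi]
        assert np.nanmean(itc[fi, sel]) > 0.9

    def test_itc_peaks_at_optimal_noise_condition(self):
        """Inverted-U: the empirical 40-Hz ITC in the response window is
        maximal at the condition mapped nearest sigma_opt (the '0' label)."""
        cfg = ss.default_config(n_trials=200)
        grid = ss.make_frequency_grid(srate=cfg.srate).subset(35.0, 45.0)
        fi = np.argmin(np.abs(grid.freqs - 40.0))
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            scores = []
            for ci, cond in enumerate(cfg.conditions):
                rng = np.random.default_rng(np.random.SeedSequence([100 + rep, ci]))
                ep = ss.generate_source_epochs(cfg, "S", "R_STG", cond, rng)
                tf = ss.morlet_tf(ep, grid)
                itc = intertrial_coherence(tf)
                sel = (tf.times >= 0.0) & (tf.times <= 0.100) & tf.valid_mask[fi]
                scores.append(np.nanmean(itc[fi, sel]))
            if cfg.conditions[int(np.argmax(scores))] == "0":
                hits += 1
        assert hits >= int(0.9 * n_rep)


class TestCoupledPair:
    def test_uncoupled_pair_is_at_null_level(self, default_grid):
        cfg = ss.default_config(n_trials=100)
        ep_i, ep_j = ss.generate_coupled_pair(
            cfg, ("R_STG", "L_SFG"), "none", (9.0, 14.0), (0.05, 0.30),
            np.random.default_rng(5), params=ss.SRProfileParams(0.0, 0.0, 1.0))
        pm = ss.cross_coherence(ss.morlet_tf(ep_i, default_grid), ss.morlet_tf(ep_j, default_grid))
        val = ss.window_mean_plv(pm, ss.WindowSpec(0.05, 0.30, 9.0, 14.0))
        # Rayleigh null for N=100 is ~0.089; allow generous sampling slack
        assert val < 0.2

    def test_locked_pair_is_near_one_inside_window(self, default_grid):
        cfg = ss.default_config(n_trials=60)
        ep_i, ep_j = ss.generate_coupled_pair(
            cfg, ("R_STG", "L_SFG"), "0", (9.0, 14.0), (0.05, 0.30),
            np.random.default_rng(6), params=ss.SRProfileParams(1e6, 0.0, 1.0))
        pm = ss.cross_coherence(ss.morlet_tf(ep_i, default_grid), ss.morlet_tf(ep_j, default_grid))
        # interior of the coupling window, past the 10-ms entry relaxation
        val = ss.window_mean_plv(pm, ss.WindowSpec(0.10, 0.28, 10.0, 13.0))
        assert val > 0.9

    def test_trial_counts_aligned(self, default_grid):
        cfg = ss.default_config(n_trials=17)
        ep_i, ep_j = ss.generate_coupled_pair(
            cfg, ("R_STG", "L_SFG"), "5", (9.0, 14.0), (0.05, 0.30),
            np.random.default_rng(7), params=ss.SRProfileParams(0.5, 1.0, 1.0))
        assert ep_i.n_trials == ep_j.n_trials == 17

    def test_band_outside_range_rejected(self):
        cfg = ss.default_config()
        with pytest.raises(ss.InvalidConfigError):
            ss.generate_coupled_pair(cfg, ("R_STG", "L_SFG"), "0", (2.0, 6.0),
                                     (0.05, 0.30), np.random.default_rng(0),
                                     params=ss.SRProfileParams(0, 1, 1))


class TestDataset:
    def test_dataset_is_deterministic(self, small_config):
        a = ss.generate_dataset(small_config)
        b = ss.generate_dataset(small_config)
        assert len(a) == len(b) == (small_config.n_subjects
                                    * len(small_config.sources)
                                    * len(small_config.conditions))
        for ea, eb in zip(a, b):
            assert (ea.subject, ea.source, ea.condition) == (eb.subject, eb.source, eb.condition)
            np.testing.assert_array_equal(ea.data, eb.data)
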