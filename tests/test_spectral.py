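"""Wavelet decomposition and ERSP: normalization, masking, baseline, bands."""

import numpy as np
import pytest

import srsync as ss
from srsync.spectral import _morlet_kernel
from srsync.windows import pixel_mask


def _cosine_epochs(f, n_trials=3, n_samples=400, srate=250.0, t_start=-0.8, amp=1.0):
    t = t_start + np.arange(n_samples) / srate
    data = np.tile(amp * np.cos(2 * np.pi * f * t), (n_trials, 1))
    return ss.EpochSet(data, srate, t_start, "S", "X", "none")


class TestFrequencyGrid:
    def test_geometric_spacing_and_endpoints(self):
        g = ss.make_frequency_grid(5.0, 55.0, 25, 3.0)
        assert g.freqs[0] == pytest.approx(5.0)
        assert g.freqs[-1] == pytest.approx(55.0)
        ratios = g.freqs[1:] / g.freqs[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_cycle_growth(self):
        g = ss.make_frequency_grid(5.0, 55.0, 25, 3.0)
        assert g.cycles[0] == pytest.approx(3.0)
        # cycles(f) = c0 * (f/f_min)**0.5 -> 9 at 45 Hz
        i = np.argmin(np.abs(g.freqs - 45.0))
        assert g.cycles[i] == pytest.approx(3.0 * np.sqrt(g.freqs[i] / 5.0))
        assert 3.0 * np.sqrt(45.0 / 5.0) == pytest.approx(9.0)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            ss.make_frequency_grid(5.0, 130.0, 10, 3.0, srate=250.0)

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            ss.make_frequency_grid(55.0, 5.0, 10, 3.0)
        with pytest.raises(ValueError):
            ss.make_frequency_grid(5.0, 55.0, 1, 3.0)


class TestMorletTF:
    def test_unit_cosine_normalization(self, default_grid):
        tf = ss.morlet_tf(_cosine_epochs(40.0), default_grid)
        fi = np.argmin(np.abs(default_grid.freqs - 40.0))
        mags = np.abs(tf.coeffs[0])
        interior = tf.valid_mask[fi]
        # the grid bin nearest 40 Hz carries the largest response ...
        t_probe = np.flatnonzero(tf.valid_mask.all(axis=0))[0]
        assert np.argmax(mags[:, t_probe]) == fi
        # ... and carries it at |coeff| close to 0.5 (bin offset from 40 Hz
        # costs a little through the Gaussian frequency response)
        assert np.abs(mags[fi, interior] - 0.5).max() < 0.01

    def test_zero_input_gives_zero(self, default_grid):
        ep = ss.EpochSet(np.zeros((2, 400)), 250.0, -0.8, "S", "X", "none")
        tf = ss.morlet_tf(ep, default_grid)
        assert np.all(tf.coeffs == 0)

    def test_linearity(self, default_grid, rng):
        data = rng.standard_normal((4, 400))
        ep1 = ss.EpochSet(data, 250.0, -0.8, "S", "X", "none")
        ep2 = ss.EpochSet(2.0 * data, 250.0, -0.8, "S", "X", "none")
        tf1 = ss.morlet_tf(ep1, default_grid)
        tf2 = ss.morlet_tf(ep2, default_grid)
        np.testing.assert_allclose(tf2.coeffs, 2.0 * tf1.coeffs, rtol=0, atol=1e-12)

    def test_epoch_shorter_than_wavelet_rejected(self, default_grid):
        ep = ss.EpochSet(np.zeros((2, 40)), 250.0, -0.08, "S", "X", "none")
        with pytest.raises(ss.UnsupportedEpochError):
            ss.morlet_tf(ep, default_grid)

    def test_valid_region_widens_with_frequency(self, default_grid):
        ep = ss.EpochSet(np.zeros((1, 400)), 250.0, -0.8, "S", "X", "none")
        tf = ss.morlet_tf(ep, default_grid)
        n_valid = tf.valid_mask.sum(axis=1)
        assert np.all(np.diff(n_valid) >= 0)  # longer wavelets -> fewer valid samples

    def test_white_noise_power_matches_kernel_energy(self, rng):
        """Mean |coeff|^2 of unit-variance white noise equals the kernel's
        squared l2 norm (within 10%), per frequency."""
        grid = ss.make_frequency_grid(srate=250.0)
        ep = ss.EpochSet(rng.standard_normal((300, 400)), 250.0, -0.8, "S", "X", "none")
        tf = ss.morlet_tf(ep, grid)
        for i in [0, 6, 12, 18, 24]:
            expected = np.sum(np.abs(_morlet_kernel(grid.freqs[i], grid.cycles[i], 250.0)) ** 2)
            observed = np.mean(np.abs(tf.coeffs[:, i, tf.valid_mask[i]]) ** 2)
            assert observed == pytest.approx(expected, rel=0.10)

    def test_phase_agrees_with_mne_reference(self, rng):
        """Independent cross-check: instantaneous phase matches MNE's Morlet
        transform on strong sinusoidal signals at interior samples."""
        mne = pytest.importorskip("mne")
        grid = ss.make_frequency_grid(srate=250.0)
        freqs = grid.freqs[[5, 12, 20]]
        cycles = grid.cycles[[5, 12, 20]]
        t = np.arange(400) / 250.0
        phases = rng.uniform(-np.pi, np.pi, (5, 3))
        x = np.stack([
            sum(np.cos(2 * np.pi * f * t + ph[i]) for i, f in enumerate(freqs))
            for ph in phases
        ])
        ref = mne.time_frequency.tfr_array_morlet(
            x[:, None, :], 250.0, freqs, n_cycles=cycles,
            output="complex", zero_mean=False, verbose=False)[:, 0]
        tf = ss.morlet_tf(ss.EpochSet(x, 250.0, -0.8, "S", "X", "none"),
                          ss.FrequencyGrid(freqs, cycles))
        diff = np.angle(np.exp(1j * (np.angle(ref) - np.angle(tf.coeffs))))
        for i in range(3):
            sel = tf.valid_mask[i]
            assert np.abs(diff[:, i, sel]).max() < 0.05


class TestERSP:
    def test_baseline_power_ratio_identity(self, rng, default_grid):
        """The trial-mean power averaged over valid baseline samples equals the
        baseline power exactly, by construction."""
        ep = ss.EpochSet(rng.standard_normal((50, 400)), 250.0, -0.8, "S", "X", "none")
        tf = ss.morlet_tf(ep, default_grid)
        emap = ss.ersp(tf, baseline_window=(-0.5, -0.3))
        power = np.mean(np.abs(tf.coeffs) ** 2, axis=0)
        in_base = (tf.times >= -0.5) & (tf.times <= -0.3)
        for i in range(len(default_grid)):
            sel = in_base & emap.valid_mask[i]
            if sel.any():
                ratio = power[i, sel] / emap.baseline_power[i]
                assert ratio.mean() == pytest.approx(1.0, rel=1e-12)
                assert abs(emap.ersp[i, sel].mean()) < 0.5  # dB mean ~0 (Jensen gap only)

    def test_amplitude_step_recovers_6db(self):
        """Doubling the oscillation amplitude at t >= 0 shows as ~+6.02 dB."""
        srate, t_start, n = 250.0, -0.8, 400
        t = t_start + np.arange(n) / srate
        rng = np.random.default_rng(11)
        trials = []
        for _ in range(20):
            ph = rng.uniform(-np.pi, np.pi)
            amp = np.where(t >= 0, 2.0, 1.0)
            trials.append(amp * np.cos(2 * np.pi * 40.0 * t + ph))
        ep = ss.EpochSet(np.array(trials), srate, t_start, "S", "X", "none")
        grid = ss.make_frequency_grid(srate=srate)
        emap = ss.ersp(ss.morlet_tf(ep, grid), baseline_window=(-0.4, -0.2))
        fi = np.argmin(np.abs(grid.freqs - 40.0))
        sel = (emap.times >= 0.15) & (emap.times <= 0.30) & emap.valid_mask[fi]
        assert emap.ersp[fi, sel].mean() == pytest.approx(10 * np.log10(4.0), abs=0.1)

    def test_zero_signal_degenerate_baseline(self, default_grid):
        ep = ss.EpochSet(np.zeros((3, 400)), 250.0, -0.8, "S", "X", "none")
        tf = ss.morlet_tf(ep, default_grid)
        with pytest.raises(ss.DegenerateBaselineError):
            ss.ersp(tf, baseline_window=(-0.5, -0.3))

    def test_edge_baseline_masks_low_frequencies(self, rng, default_grid):
        """With the study epoch (-150..450 ms) the baseline sits at the epoch
        edge: low-frequency rows have no valid baseline sample and are masked,
        while the gamma range stays analyzable."""
        cfg = ss.default_config(n_trials=30)
        ep = ss.generate_source_epochs(cfg, "S", "R_STG", "0", rng)
        emap = ss.ersp(ss.morlet_tf(ep, default_grid))
        row_ok = emap.valid_mask.any(axis=1)
        assert not row_ok[0]                          # 5 Hz: unanalyzable
        assert row_ok[np.abs(emap.freqs - 40).argmin()]   # 40 Hz: analyzable


class TestCustomBand:
    @staticmethod
    def _ersp_map(values, freqs, times):
        return ss.ERSPMap(ersp=values, baseline_power=np.ones(len(freqs)),
                          baseline_window=(-0.15, -0.05), freqs=freqs, times=times,
                          valid_mask=np.ones_like(values, dtype=bool))

    def test_band_brackets_injected_peak(self):
        freqs = np.geomspace(5, 55, 25)
        times = np.arange(0.0, 0.2, 0.004)
        vals = np.zeros((25, len(times)))
        vals += 5.0 * np.exp(-((freqs[:, None] - 38.0) ** 2) / (2 * 3.0**2))
        band = ss.custom_band(self._ersp_map(vals, freqs, times), (0.0, 0.1))
        assert band[0] <= 38.0 <= band[1]
        assert 30.0 <= band[0] < band[1] <= 50.0

    def test_no_response_falls_back(self):
        freqs = np.geomspace(5, 55, 25)
        times = np.arange(0.0, 0.2, 0.004)
        band = ss.custom_band(self._ersp_map(np.zeros((25, len(times))), freqs, times), (0.0, 0.1))
        assert band == (35.0, 45.0)

    def test_tie_breaks_to_lower_frequency(self):
        freqs = np.geomspace(5, 55, 25)
        times = np.arange(0.0, 0.2, 0.004)
        vals = np.zeros((25, len(times)))
        lo = np.argmin(np.abs(freqs - 33.0))
        hi = np.argmin(np.abs(freqs - 46.0))
        vals[lo] = vals[hi] = 4.0
        band = ss.custom_band(self._ersp_map(vals, freqs, times), (0.0, 0.1))
        assert band[0] <= freqs[lo] <= band[1]
        assert band[1] < freqs[hi]
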