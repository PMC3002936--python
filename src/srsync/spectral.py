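"""Morlet wavelet time-frequency decomposition and ERSP maps.

Conventions
-----------
* The frequency grid is geometric (log-spaced) between ``f_min`` and ``f_max``
  with wavelet cycle counts growing as ``c0 * (f/f_min)**0.5`` — slower than
  linear, so temporal resolution improves with frequency while spectral
  bandwidth stays proportional to frequency.
* Wavelets are complex Morlet kernels with temporal standard deviation
  ``sigma_t = cycles/(2 pi f)``, truncated at ±2.5 sigma_t and normalized to
  unit kernel sum, so a unit-amplitude cosine at the centre frequency yields
  coefficients of modulus 0.5.
* No zero padding: a coefficient is *valid* only where the truncated wavelet
  fits entirely inside the epoch.  Invalid edge pixels are masked and excluded
  from every downstream window statistic.  Because epochs start at the
  baseline edge, low frequencies may have no valid baseline samples; such
  frequency rows are masked invalid in the ERSP map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .exceptions import DegenerateBaselineError, UnsupportedEpochError
from .synth import EpochSet
from .windows import BASELINE_WINDOW, RESPONSE_WINDOW, WindowSpec, pixel_mask

__all__ = [
    "FrequencyGrid",
    "TFMap",
    "ERSPMap",
    "make_frequency_grid",
    "morlet_tf",
    "ersp",
    "custom_band",
    "intertrial_coherence",
]

#: Gaussian-envelope truncation, in units of sigma_t.
KERNEL_TRUNC = 2.5


@dataclass(frozen=True)
class FrequencyGrid:
    """Log-spaced centre frequencies with per-frequency cycle counts."""

    freqs: np.ndarray
    cycles: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        cycles = np.asarray(self.cycles, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "cycles", cycles)
        if freqs.ndim != 1 or len(freqs) < 1 or len(freqs) != len(cycles):
            raise ValueError("freqs and cycles must be 1-d arrays of equal length")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(cycles <= 0) or np.any(np.diff(cycles) < 0):
            raise ValueError("cycles must be positive and non-decreasing")

    def __len__(self) -> int:
        return len(self.freqs)

    def subset(self, f_lo: float, f_hi: float) -> "FrequencyGrid":
        """Sub-grid of bins with centre frequency in [f_lo, f_hi] (cycle
        counts preserved, so coefficients match the full-grid decomposition)."""
        sel = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if not sel.any():
            raise ValueError(f"no grid frequencies inside [{f_lo}, {f_hi}]")
        return FrequencyGrid(self.freqs[sel], self.cycles[sel])


def make_frequency_grid(
    f_min: float = 5.0,
    f_max: float = 55.0,
    n_bins: int = 25,
    c0: float = 3.0,
    srate: float | None = None,
) -> FrequencyGrid:
    """Geometric frequency grid with cycles(f) = c0 * (f/f_min)**0.5."""
    if not (0 < f_min < f_max):
        raise ValueError(f"need 0 < f_min < f_max, got {f_min}, {f_max}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if c0 <= 0:
        raise ValueError("c0 must be > 0")
    if srate is not None and f_max >= srate / 2:
        raise ValueError(f"f_max={f_max} must be below the Nyquist frequency {srate / 2}")
    freqs = np.geomspace(f_min, f_max, n_bins)
    cycles = c0 * np.sqrt(freqs / f_min)
    return FrequencyGrid(freqs, cycles)


@dataclass(frozen=True)
class TFMap:
    """Complex wavelet coefficients, trials x freqs x times, with validity mask."""

    coeffs: np.ndarray           # complex, (n_trials, n_freqs, n_times)
    valid_mask: np.ndarray       # bool, (n_freqs, n_times)
    times: np.ndarray            # s
    grid: FrequencyGrid

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    @property
    def freqs(self) -> np.ndarray:
        return self.grid.freqs


def _morlet_kernel(f: float, cycles: float, srate: float) -> np.ndarray:
    """Truncated, sum-normalized complex Morlet kernel."""
    sigma_t = cycles / (2.0 * np.pi * f)
    half = int(round(KERNEL_TRUNC * sigma_t * srate))
    n = np.arange(-half, half + 1)
    g = np.exp(-((n / srate) ** 2) / (2.0 * sigma_t**2))
    g /= g.sum()
    return g * np.exp(2j * np.pi * f * n / srate)


def morlet_tf(epochs: EpochSet, grid: FrequencyGrid) -> TFMap:
    """Wavelet-decompose every trial on ``grid``.

    Coefficient at (trial k, freq f, time t) is the correlation of trial k
    with the Morlet kernel centred at t.  A unit cosine at f gives
    ``|coeff| = 0.5`` at valid samples; the map is linear in the input.
    """
    if grid.freqs[-1] >= epochs.srate / 2:
        raise UnsupportedEpochError(
            f"grid reaches {grid.freqs[-1]} Hz >= Nyquist {epochs.srate / 2} Hz"
        )
    n_trials, n_times = epochs.data.shape
    n_freqs = len(grid)
    coeffs = np.empty((n_trials, n_freqs, n_times), dtype=complex)
    valid = np.zeros((n_freqs, n_times), dtype=bool)
    for i, (f, c) in enumerate(zip(grid.freqs, grid.cycles)):
        kernel = _morlet_kernel(f, c, epochs.srate)
        half = (len(kernel) - 1) // 2
        if 2 * half + 1 > n_times:
            raise UnsupportedEpochError(
                f"epoch of {n_times} samples shorter than the wavelet at {f:.3g} Hz "
                f"({2 * half + 1} samples)"
            )
        # correlation: coeff[t] = sum_n x[t+n] conj(psi[n])
        coeffs[:, i, :] = fftconvolve(
            epochs.data, np.conj(kernel[::-1])[None, :], mode="same", axes=1
        )
        valid[i, half : n_times - half] = True
    if not valid.any(axis=1).all():
        raise UnsupportedEpochError("some frequency has no sample with full wavelet support")
    return TFMap(coeffs=coeffs, valid_mask=valid, times=epochs.times.copy(), grid=grid)


@dataclass(frozen=True)
class ERSPMap:
    """Baseline-normalized dB power per (frequency, time) pixel."""

    ersp: np.ndarray             # dB, (n_freqs, n_times); NaN where invalid
    baseline_power: np.ndarray   # power units, per frequency; NaN if no baseline
    baseline_window: tuple[float, float]
    freqs: np.ndarray
    times: np.ndarray
    valid_mask: np.ndarray


def ersp(tf: TFMap, baseline_window: tuple[float, float] = BASELINE_WINDOW) -> ERSPMap:
    """Event-related spectral perturbation relative to the pre-stimulus baseline.

    ``P(f,t)`` is the trial-mean of ``|coeff|**2``; baseline power per
    frequency is the mean of ``P`` over the *valid* samples inside
    ``baseline_window``; the map is ``10*log10(P/baseline)``.  Frequencies
    with no valid baseline sample are masked invalid; a zero baseline raises
    :class:`DegenerateBaselineError`.
    """
    b0, b1 = baseline_window
    power = np.mean(np.abs(tf.coeffs) ** 2, axis=0)
    in_base = (tf.times >= b0) & (tf.times <= b1)
    valid = tf.valid_mask.copy()
    n_freqs = len(tf.grid)
    baseline = np.full(n_freqs, np.nan)
    for i in range(n_freqs):
        sel = in_base & valid[i]
        if not sel.any():
            valid[i] = False
            continue
        baseline[i] = power[i, sel].mean()
        if baseline[i] == 0.0:
            raise DegenerateBaselineError(
                f"baseline power is exactly zero at {tf.grid.freqs[i]:.3g} Hz"
            )
    if not valid.any():
        raise DegenerateBaselineError(
            f"no frequency has valid samples inside the baseline window [{b0}, {b1}] s"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 10.0 * np.log10(power / baseline[:, None])
    out[~valid] = np.nan
    return ERSPMap(
        ersp=out,
        baseline_power=baseline,
        baseline_window=(b0, b1),
        freqs=tf.grid.freqs.copy(),
        times=tf.times.copy(),
        valid_mask=valid,
    )


def custom_band(
    deviant_ersp: ERSPMap,
    response_window: tuple[float, float] = RESPONSE_WINDOW,
    search_band: tuple[float, float] = (30.0, 50.0),
    fallback: tuple[float, float] = (35.0, 45.0),
) -> tuple[float, float]:
    """Subject-specific gamma band from the response to audible deviants.

    Finds the peak ERSP pixel inside ``search_band`` x ``response_window`` and
    returns the contiguous frequency span around the peak whose per-frequency
    response profile (max over window times) stays >= 50% of the peak dB.
    Ties go to the lower frequency.  If there is no positive response (or no
    valid pixels), returns ``fallback`` (35-45 Hz by convention).
    """
    win = WindowSpec(response_window[0], response_window[1],
                     search_band[0], search_band[1], "custom-band search")
    sel = pixel_mask(deviant_ersp.freqs, deviant_ersp.times, win, deviant_ersp.valid_mask)
    if not sel.any():
        return fallback
    masked = np.where(sel, deviant_ersp.ersp, -np.inf)
    profile = masked.max(axis=1)                        # per-frequency response
    fidx = np.flatnonzero(np.isfinite(profile))
    peak_i = fidx[np.argmax(profile[fidx])]             # argmax -> lowest-f tie-break
    peak = profile[peak_i]
    if peak <= 0.0:
        return fallback
    lo = hi = peak_i
    while lo - 1 in fidx and profile[lo - 1] >= 0.5 * peak:
        lo -= 1
    while hi + 1 in fidx and profile[hi + 1] >= 0.5 * peak:
        hi += 1
    return (float(deviant_ersp.freqs[lo]), float(deviant_ersp.freqs[hi]))


def intertrial_coherence(tf: TFMap) -> np.ndarray:
    """Inter-trial phase coherence |mean_k W_k/|W_k|| per pixel (NaN where
    invalid or where any trial has a zero coefficient)."""
    mag = np.abs(tf.coeffs)
    with np.errstate(divide="ignore", invalid="ignore"):
        phasors = np.where(mag > 0, tf.coeffs / mag, np.nan)
    itc = np.abs(phasors.mean(axis=0))
    itc[~tf.valid_mask] = np.nan
    return itc
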