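"""Trial-wise cross-coherence (phase-locking value) between two sources.

For wavelet coefficients ``W_i,k(f,t)`` of sources i, j over trials
``k = 1..N``, the cross-coherence at a pixel is::

    C_ij(f,t) = | (1/N) sum_k  W_i,k conj(W_j,k) / |W_i,k conj(W_j,k)| |

Each trial contributes one *unit* phasor of the instantaneous phase
difference, so the statistic depends only on phase differences (0 = no
locking, 1 = perfect locking) and is invariant to any positive per-trial or
per-pixel amplitude scaling of either input.  Trials with a zero coefficient
at a pixel carry no phase and are excluded there, with the exclusion count
recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AlignmentError, EmptyWindowError
from .spectral import TFMap
from .windows import WindowSpec, pixel_mask

__all__ = ["PLVMap", "cross_coherence", "window_mean_plv"]


@dataclass(frozen=True)
class PLVMap:
    """Cross-coherence per pixel for one source pair and condition."""

    plv: np.ndarray              # (n_freqs, n_times) in [0, 1]; NaN where invalid
    valid_mask: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    pair: tuple[str, str]
    condition: str
    n_trials: int
    n_dropped: int = 0           # total (trial, pixel) phasors excluded as zero


def _unit_phasors(coeffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit phasors of complex coefficients; zeros map to 0 with a False flag."""
    mag = np.abs(coeffs)
    nonzero = mag > 0
    out = np.zeros_like(coeffs)
    np.divide(coeffs, mag, out=out, where=nonzero)
    return out, nonzero


def _check_aligned(tf_i: TFMap, tf_j: TFMap) -> None:
    if tf_i.coeffs.shape != tf_j.coeffs.shape:
        raise AlignmentError(
            f"coefficient shapes differ: {tf_i.coeffs.shape} vs {tf_j.coeffs.shape}"
        )
    if not np.allclose(tf_i.grid.freqs, tf_j.grid.freqs):
        raise AlignmentError("frequency grids differ")
    if not np.allclose(tf_i.times, tf_j.times):
        raise AlignmentError("time axes differ")


def cross_coherence(
    tf_i: TFMap,
    tf_j: TFMap,
    pair: tuple[str, str] = ("i", "j"),
    condition: str = "",
) -> PLVMap:
    """Phase-only cross-coherence map between two aligned decompositions."""
    _check_aligned(tf_i, tf_j)
    prod = tf_i.coeffs * np.conj(tf_j.coeffs)
    u, nonzero = _unit_phasors(prod)
    count = nonzero.sum(axis=0)
    with np.errstate(invalid="ignore"):
        plv = np.abs(u.sum(axis=0)) / count
    valid = tf_i.valid_mask & tf_j.valid_mask & (count > 0)
    plv = np.where(valid, plv, np.nan)
    n_dropped = int((~nonzero).sum())
    return PLVMap(
        plv=plv,
        valid_mask=valid,
        freqs=tf_i.grid.freqs.copy(),
        times=tf_i.times.copy(),
        pair=tuple(pair),
        condition=condition,
        n_trials=tf_i.n_trials,
        n_dropped=n_dropped,
    )


def window_mean_plv(plv_map: PLVMap, window: WindowSpec) -> float:
    """Arithmetic mean of cross-coherence over the valid pixels of a window."""
    sel = pixel_mask(plv_map.freqs, plv_map.times, window, plv_map.valid_mask)
    if not sel.any():
        raise EmptyWindowError(f"no valid pixels inside window {window}")
    return float(plv_map.plv[sel].mean())
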