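"""Time-frequency window specifications and pixel selection helpers.

A "pixel" is one (frequency, time) cell of a wavelet decomposition grid.
Windows are rectangles in (time, frequency); all window sums and means in the
pipeline run over the *valid* pixels of a window only (edge samples without
full wavelet support are excluded upstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Band conventions used throughout the analysis (Hz).
THETA = (4.0, 8.0)
ALPHA = (9.0, 14.0)
GAMMA = (30.0, 50.0)

#: Pre-stimulus baseline window (s, relative to stimulus onset).
BASELINE_WINDOW = (-0.150, -0.050)
#: 40-Hz transient response window (s).
RESPONSE_WINDOW = (0.0, 0.100)


@dataclass(frozen=True)
class WindowSpec:
    """A rectangular time-frequency window.

    Parameters
    ----------
    t0, t1 : float
        Window start/end in seconds relative to stimulus onset.
    f0, f1 : float
        Lower/upper frequency bound in Hz (inclusive).
    label : str
        Free-form tag, e.g. ``"response"``, ``"alpha"``.
    """

    t0: float
    t1: float
    f0: float
    f1: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.t0 < self.t1):
            raise ValueError(f"window requires t0 < t1, got [{self.t0}, {self.t1}]")
        if not (self.f0 < self.f1):
            raise ValueError(f"window requires f0 < f1, got [{self.f0}, {self.f1}]")


def pixel_mask(
    freqs: np.ndarray,
    times: np.ndarray,
    window: WindowSpec,
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean (n_freqs, n_times) mask of valid pixels inside ``window``."""
    freqs = np.asarray(freqs, dtype=float)
    times = np.asarray(times, dtype=float)
    fsel = (freqs >= window.f0) & (freqs <= window.f1)
    tsel = (times >= window.t0) & (times <= window.t1)
    mask = np.outer(fsel, tsel)
    if valid_mask is not None:
        mask &= np.asarray(valid_mask, dtype=bool)
    return mask
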