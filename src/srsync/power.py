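"""Normalized power-ratio SR curves and the per-subject / group SR criteria.

The 40-Hz transient response is summarized per {subject, source, condition} by
summing ERSP (dB) over a time-frequency window (response window x gamma band)
and exponentiating the sum back to a power ratio; dividing each subject's
six-condition curve by its maximum gives the normalized SR curve in (0, 1].
A subject "shows SR" when the curve's unique maximum falls at an added-noise
condition.  At the group level a condition is flagged when its mean normalized
ratio departs from the no-noise mean by more than two standard errors, and —
more stringently — when a two-sided Dunnett many-to-one comparison against the
no-noise control rejects at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .exceptions import EmptyWindowError, InsufficientDataError
from .spectral import ERSPMap
from .windows import WindowSpec, pixel_mask

__all__ = [
    "SRCurve",
    "window_power_ratio",
    "normalize_curve",
    "detect_sr",
    "group_sr_stats",
    "sr_count_table",
]

_DUNNETT_MC_SEED = 20101216  # fixed: critical values must be reproducible
_DUNNETT_MC_DRAWS = 100_000


@dataclass(frozen=True)
class SRCurve:
    """Normalized power-ratio curve across noise conditions for one series."""

    subject: str
    source: str
    conditions: tuple[str, ...]
    raw_ratio: np.ndarray
    norm_ratio: np.ndarray
    ear: str = "left"
    band_mode: str = "broad"

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_ratio, dtype=float)
        norm = np.asarray(self.norm_ratio, dtype=float)
        object.__setattr__(self, "raw_ratio", raw)
        object.__setattr__(self, "norm_ratio", norm)
        if len(raw) != len(self.conditions) or len(norm) != len(self.conditions):
            raise ValueError("ratio arrays must match the condition labels")


def window_power_ratio(ersp_map: ERSPMap, window: WindowSpec) -> float:
    """Power ratio of one time-frequency window: 10**(sum of window dB / 10).

    Summing dB across pixels and exponentiating once makes the ratio a product
    of per-pixel power ratios.  Only valid pixels contribute.
    """
    sel = pixel_mask(ersp_map.freqs, ersp_map.times, window, ersp_map.valid_mask)
    if not sel.any():
        raise EmptyWindowError(f"no valid pixels inside window {window}")
    s_db = float(ersp_map.ersp[sel].sum())
    return 10.0 ** (s_db / 10.0)


def normalize_curve(
    conditions,
    raw_ratios,
    subject: str = "",
    source: str = "",
    ear: str = "left",
    band_mode: str = "broad",
) -> SRCurve:
    """Divide raw power ratios by their maximum; argmax is preserved."""
    conditions = tuple(conditions)
    raw = np.asarray(raw_ratios, dtype=float)
    if len(conditions) < 2:
        raise InsufficientDataError("need >= 2 conditions to normalize")
    if np.any(raw <= 0) or not np.all(np.isfinite(raw)):
        raise ValueError("raw power ratios must be positive and finite")
    return SRCurve(subject, source, conditions, raw, raw / raw.max(),
                   ear=ear, band_mode=band_mode)


def detect_sr(curve: SRCurve, zero_label: str = "none") -> dict:
    """Per-subject SR call: the curve's *unique* maximum at an added-noise level.

    Ties (including any tie involving the no-noise condition) are counted as
    no SR — the conservative reading.
    """
    if zero_label not in curve.conditions:
        raise ValueError(f"zero-noise label {zero_label!r} missing from curve conditions")
    m = curve.norm_ratio.max()
    at_max = np.flatnonzero(curve.norm_ratio == m)
    peak_condition = curve.conditions[at_max[0]]
    is_sr = len(at_max) == 1 and peak_condition != zero_label
    return {"is_sr": bool(is_sr), "peak_condition": peak_condition}


@lru_cache(maxsize=None)
def _dunnett_critical_value(n: int, m: int, alpha: float,
                            n_draws: int = _DUNNETT_MC_DRAWS) -> float:
    """Two-sided critical value for max |t| over m paired many-to-one contrasts.

    Monte-Carlo of the exact null pipeline: draw iid normal data for n subjects
    x (m+1) conditions, form within-subject differences vs the control, pool
    the variance over contrasts (df = m*(n-1)), and take the (1-alpha) quantile
    of max_c |t_c|.  Cached per (n, m, alpha).
    """
    rng = np.random.default_rng(_DUNNETT_MC_SEED)
    crit_max = np.empty(n_draws)
    chunk = 20_000
    done = 0
    while done < n_draws:
        r = min(chunk, n_draws - done)
        x = rng.standard_normal((r, n, m + 1))
        d = x[:, :, 1:] - x[:, :, :1]
        dbar = d.mean(axis=1)
        resid = d - dbar[:, None, :]
        s2 = (resid**2).sum(axis=(1, 2)) / (m * (n - 1))
        t = dbar * np.sqrt(n) / np.sqrt(s2)[:, None]
        crit_max[done : done + r] = np.abs(t).max(axis=1)
        done += r
    return float(np.quantile(crit_max, 1.0 - alpha))


def group_sr_stats(curves, zero_label: str = "none", alpha: float = 0.05) -> pd.DataFrame:
    """Group summary of normalized SR curves across subjects.

    Returns a DataFrame indexed by condition with columns ``mean``, ``se``,
    ``flag_2se`` (|mean(c) - mean(zero)| > 2*SE(c)) and ``flag_dunnett``
    (two-sided Dunnett many-to-one vs the no-noise control at ``alpha``, on
    within-subject differences with pooled variance and Monte-Carlo critical
    values).
    """
    curves = list(curves)
    if len(curves) < 3:
        raise InsufficientDataError(f"need >= 3 subjects, got {len(curves)}")
    conditions = curves[0].conditions
    if any(c.conditions != conditions for c in curves):
        raise ValueError("all curves must share the same condition ordering")
    if zero_label not in conditions:
        raise ValueError(f"zero-noise label {zero_label!r} missing")
    x = np.stack([c.norm_ratio for c in curves])       # subjects x conditions
    n = x.shape[0]
    mean = x.mean(axis=0)
    se = x.std(axis=0, ddof=1) / np.sqrt(n)
    zi = conditions.index(zero_label)
    flag_2se = np.abs(mean - mean[zi]) > 2.0 * se
    flag_2se[zi] = False

    added = [i for i in range(len(conditions)) if i != zi]
    m = len(added)
    d = x[:, added] - x[:, [zi]]
    dbar = d.mean(axis=0)
    s2 = ((d - dbar) ** 2).sum() / (m * (n - 1))
    crit = _dunnett_critical_value(n, m, alpha)
    flag_dunnett = np.zeros(len(conditions), dtype=bool)
    if s2 > 0:
        t = dbar * np.sqrt(n) / np.sqrt(s2)
        flag_dunnett[added] = np.abs(t) > crit
    else:  # zero pooled variance: any nonzero mean difference is infinitely many SEs
        flag_dunnett[added] = dbar != 0.0

    return pd.DataFrame(
        {"mean": mean, "se": se, "flag_2se": flag_2se, "flag_dunnett": flag_dunnett},
        index=pd.Index(conditions, name="condition"),
    )


def sr_count_table(records: pd.DataFrame) -> pd.DataFrame:
    """Counts of subjects showing SR, by source x (ear, band mode).

    ``records`` needs columns ``subject, source, ear, band_mode, is_sr`` (one
    row per curve).  Returns a table of ``"k/n"`` strings with sources as rows
    and (ear, band_mode) column pairs.
    """
    required = {"subject", "source", "ear", "band_mode", "is_sr"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    grouped = records.groupby(["source", "ear", "band_mode"])["is_sr"].agg(["sum", "count"])
    cell = grouped.apply(lambda r: f"{int(r['sum'])}/{int(r['count'])}", axis=1)
    table = cell.unstack(["ear", "band_mode"])
    return table.fillna("0/0")
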