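"""Two-criterion resampling inference for SR in inter-regional phase locking.

Criterion 1 — condition difference.  All window pixel cross-coherence values
of all subjects are pooled for the added-noise condition and for the no-noise
condition; the observed mean difference is compared with 1000 surrogate
differences from random bipartitions of the combined pool.  Exceeding *all*
surrogates is significant at p < 0.001 (one-sided: added > none, the SR
direction).

Criterion 2 — non-zero locking.  Each subject's coherence is masked per pixel
at p < 0.01 against 200 trial-pairing surrogates (shuffling one source's trial
order, which destroys trial pairing while preserving both marginals); the
group is masked with an exact binomial rule: a pixel is group-significant when
k-or-more of n subjects are individually significant, with the binomial tail
P(X >= k | n, 0.01) kept below 0.001.  Isolated pixels are discarded — only
4-connected clusters of at least ``min_cluster`` pixels count.

A (pair, band, window) cell is then classified:

* red  — noise-induced locking: some added-noise condition passes both
  criteria while the no-noise condition shows no reliable locking;
* blue — tonic locking modulated by noise: locking is reliably non-zero in the
  no-noise condition and most added-noise conditions, with at least one
  significant condition difference;
* gray — anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .exceptions import (
    AlignmentError,
    InfeasibleError,
    InsufficientDataError,
    ResolutionError,
)
from .plv import _check_aligned, _unit_phasors
from .spectral import TFMap

__all__ = [
    "PermTestResult",
    "GroupMask",
    "PairClassification",
    "permutation_condition_test",
    "single_pair_surrogate_mask",
    "binomial_kmin",
    "binomial_group_mask",
    "classify_pair_window",
]


@dataclass(frozen=True)
class PermTestResult:
    observed_diff: float
    surrogate_diffs: np.ndarray
    significant: bool
    p_bound: float


def permutation_condition_test(
    values_added: np.ndarray,
    values_none: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> PermTestResult:
    """Pooled permutation test of added-noise vs no-noise cross-coherence.

    Surrogates are random bipartitions of the combined pool into groups of the
    original sizes; the observed mean difference is significant (one-sided,
    p < 1/(n_perm+1)) only if it exceeds every surrogate difference.
    """
    a = np.asarray(values_added, dtype=float).ravel()
    b = np.asarray(values_none, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both condition pools must be non-empty")
    if rng is None:
        rng = np.random.default_rng()
    observed = float(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    mat = rng.permuted(np.broadcast_to(pool, (n_perm, pool.size)), axis=1)
    diffs = mat[:, : a.size].mean(axis=1) - mat[:, a.size :].mean(axis=1)
    significant = observed > diffs.max()
    p_bound = (1 + int(np.sum(diffs >= observed))) / (n_perm + 1)
    return PermTestResult(observed, diffs, bool(significant), float(p_bound))


def single_pair_surrogate_mask(
    tf_i: TFMap,
    tf_j: TFMap,
    n_shuffle: int = 200,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
    region_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel significance of one subject's cross-coherence vs trial shuffling.

    Surrogate maps are built by permuting source j's trial order relative to
    source i — trial pairing is destroyed, marginal statistics preserved, and
    any locking that is purely stimulus-locked (identical across trials)
    survives shuffling and therefore can never be flagged.  A pixel is
    significant when its empirical p, ``(1 + #{surrogate >= observed}) /
    (n_shuffle + 1)``, is <= ``alpha`` (for 200 shuffles at alpha = 0.01 the
    observed value must exceed the 2nd-largest surrogate).

    ``region_mask`` restricts the evaluation to a pixel subset (the returned
    full-grid mask is False outside it).
    """
    _check_aligned(tf_i, tf_j)
    if (n_shuffle + 1) * alpha < 1.0:
        raise ResolutionError(
            f"{n_shuffle} shuffles cannot resolve alpha={alpha} "
            f"(need n_shuffle >= 1/alpha - 1)"
        )
    if rng is None:
        rng = np.random.default_rng()
    shape = tf_i.valid_mask.shape
    region = tf_i.valid_mask & tf_j.valid_mask
    if region_mask is not None:
        if region_mask.shape != shape:
            raise AlignmentError("region_mask shape mismatch")
        region &= region_mask.astype(bool)
    out = np.zeros(shape, dtype=bool)
    if not region.any():
        return out

    fi, ti = np.nonzero(region)
    u_i, nz_i = _unit_phasors(tf_i.coeffs[:, fi, ti])     # (trials, n_px)
    u_j, nz_j = _unit_phasors(tf_j.coeffs[:, fi, ti])
    both = nz_i & nz_j
    count = both.sum(axis=0)
    ok = count > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.abs((u_i * np.conj(u_j)).sum(axis=0)) / count

    n_trials = tf_i.n_trials
    exceed = np.zeros(len(fi), dtype=int)
    for _ in range(n_shuffle):
        perm = rng.permutation(n_trials)
        uj = u_j[perm]
        cnt = (nz_i & nz_j[perm]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            surr = np.abs((u_i * np.conj(uj)).sum(axis=0)) / cnt
        exceed += (surr >= observed)
    p_emp = (1 + exceed) / (n_shuffle + 1)
    sig = ok & (p_emp <= alpha)
    out[fi, ti] = sig
    return out


def binomial_kmin(n: int, p: float = 0.01, alpha: float = 0.001) -> int:
    """Smallest k with P(Binomial(n, p) >= k) < alpha (exact tail)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    if alpha >= 1.0:
        return 0
    for k in range(n + 1):
        if stats.binom.sf(k - 1, n, p) < alpha:
            return k
    raise InfeasibleError(
        f"no k <= n={n} achieves binomial tail < alpha={alpha} at p={p}"
    )


@dataclass(frozen=True)
class GroupMask:
    counts: np.ndarray           # per-pixel count of individually significant subjects
    k_min: int
    mask: np.ndarray             # after the contiguity filter
    clusters: list = field(default_factory=list)   # list of (rows, cols) index arrays

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def binomial_group_mask(
    individual_masks,
    p: float = 0.01,
    alpha: float = 0.001,
    min_cluster: int = 3,
) -> GroupMask:
    """Group-level significance from per-subject pixel masks.

    A pixel passes when at least ``binomial_kmin(n, p, alpha)`` of the n
    subjects are individually significant there; surviving pixels are then
    filtered to 4-connected clusters of at least ``min_cluster`` pixels.
    """
    masks = [np.asarray(m, dtype=bool) for m in individual_masks]
    if len(masks) < 2:
        raise InsufficientDataError("need masks from >= 2 subjects")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise AlignmentError("subject masks are on different grids")
    counts = np.sum(masks, axis=0)
    k_min = binomial_kmin(len(masks), p, alpha)
    raw = counts >= k_min
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, n_lab = ndimage.label(raw, structure=structure)
    mask = np.zeros(shape, dtype=bool)
    clusters = []
    for lab in range(1, n_lab + 1):
        idx = np.nonzero(labels == lab)
        if len(idx[0]) >= min_cluster:
            mask[idx] = True
            clusters.append(idx)
    return GroupMask(counts=counts, k_min=k_min, mask=mask, clusters=clusters)


@dataclass(frozen=True)
class PairClassification:
    pair: tuple[str, str]
    band: tuple[float, float]
    window: tuple[float, float]
    category: str                               # "red" | "blue" | "gray"
    nonzero_conditions: frozenset
    perm_significant_conditions: frozenset


def classify_pair_window(
    nonzero_conditions,
    perm_significant_conditions,
    zero_label: str,
    conditions,
    pair: tuple[str, str] = ("i", "j"),
    band: tuple[float, float] = (0.0, 0.0),
    window: tuple[float, float] = (0.0, 0.0),
) -> PairClassification:
    """Three-way summary of one (pair, band, window) cell.

    red  — some added-noise condition is both permutation-significant vs
           no-noise and reliably non-zero, while no-noise locking is absent;
    blue — no-noise locking is reliably non-zero, at least half the added-noise
           conditions are too, and some condition difference is significant;
    gray — otherwise.
    """
    nonzero = frozenset(nonzero_conditions)
    perm = frozenset(perm_significant_conditions)
    conditions = list(conditions)
    added = [c for c in conditions if c != zero_label]
    if not added:
        raise ValueError("need at least one added-noise condition")
    red = bool(perm & nonzero & set(added)) and zero_label not in nonzero
    blue = (
        zero_label in nonzero
        and 2 * len(nonzero & set(added)) >= len(added)
        and len(perm) > 0
    )
    category = "red" if red else ("blue" if blue else "gray")
    return PairClassification(
        pair=tuple(pair), band=tuple(band), window=tuple(window),
        category=category, nonzero_conditions=nonzero, perm_significant_conditions=perm,
    )
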