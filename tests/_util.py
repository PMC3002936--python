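"""Shared test oracles and fixtures builders.

The oracles here are deliberately independent of the library's vectorized
implementations: plain loops and closed-form enumerations.
"""

from __future__ import annotations

import math

import numpy as np

import srsync as ss


def make_tfmap(coeffs: np.ndarray, srate: float = 250.0, t_start: float = 0.0,
               freqs: np.ndarray | None = None) -> ss.TFMap:
    """Wrap raw complex coefficients (trials x freqs x times) in a TFMap with
    an all-valid mask — for tests that probe phase statistics directly."""
    coeffs = np.asarray(coeffs, dtype=complex)
    n_trials, n_freqs, n_times = coeffs.shape
    if freqs is None:
        freqs = np.geomspace(8.0, 48.0, n_freqs) if n_freqs > 1 else np.array([40.0])
    grid = ss.FrequencyGrid(np.asarray(freqs, float), 3.0 * np.sqrt(np.asarray(freqs) / freqs[0]))
    times = t_start + np.arange(n_times) / srate
    return ss.TFMap(coeffs=coeffs, valid_mask=np.ones((n_freqs, n_times), bool),
                    times=times, grid=grid)


def plv_loop_oracle(coeffs_i: np.ndarray, coeffs_j: np.ndarray) -> np.ndarray:
    """Direct loop-over-trials phase-difference PLV, one pixel at a time."""
    n_trials, n_freqs, n_times = coeffs_i.shape
    out = np.full((n_freqs, n_times), np.nan)
    for fi in range(n_freqs):
        for ti in range(n_times):
            acc = 0.0 + 0.0j
            count = 0
            for k in range(n_trials):
                z = coeffs_i[k, fi, ti] * np.conj(coeffs_j[k, fi, ti])
                if abs(z) > 0:
                    acc += z / abs(z)
                    count += 1
            if count:
                out[fi, ti] = abs(acc) / count
    return out


def binom_tail_enum(n: int, p: float, k: int) -> float:
    """Exact P(Binomial(n, p) >= k) by term-wise enumeration."""
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def kmin_enum_oracle(n: int, p: float, alpha: float) -> int | None:
    """Smallest k <= n with the enumerated tail < alpha; None if infeasible."""
    for k in range(n + 1):
        if binom_tail_enum(n, p, k) < alpha:
            return k
    return None


ALPHA_BAND = (9.0, 14.0)
COUPLING_WINDOW = (0.05, 0.30)
COUPLED_PAIR = ("R_STG", "L_SFG")


def classify_alpha_cell(params: ss.SRProfileParams, seed: int,
                        n_subjects: int = 10, n_trials: int = 100) -> ss.PairClassification:
    """Run the full two-criterion inference for one coupled (pair, band, window)
    cell across subjects and conditions, using the alpha sub-grid."""
    cfg = ss.default_config(n_subjects=n_subjects, n_trials=n_trials)
    grid = ss.make_frequency_grid(srate=cfg.srate).subset(*ALPHA_BAND)
    win = ss.WindowSpec(COUPLING_WINDOW[0], COUPLING_WINDOW[1], *ALPHA_BAND, "alpha cell")
    conditions = cfg.conditions
    pooled: dict[str, list] = {c: [] for c in conditions}
    masks: dict[str, list] = {c: [] for c in conditions}
    for si in range(n_subjects):
        for ci, cond in enumerate(conditions):
            rng = np.random.default_rng(np.random.SeedSequence([seed, si, ci]))
            ep_i, ep_j = ss.generate_coupled_pair(
                cfg, COUPLED_PAIR, cond, ALPHA_BAND, COUPLING_WINDOW, rng, params=params
            )
            tf_i, tf_j = ss.morlet_tf(ep_i, grid), ss.morlet_tf(ep_j, grid)
            pmap = ss.cross_coherence(tf_i, tf_j, pair=COUPLED_PAIR, condition=cond)
            from srsync.windows import pixel_mask
            sel = pixel_mask(pmap.freqs, pmap.times, win, pmap.valid_mask)
            pooled[cond].append(pmap.plv[sel])
            masks[cond].append(ss.single_pair_surrogate_mask(
                tf_i, tf_j, rng=rng, region_mask=sel))
    nonzero = {c for c in conditions
               if ss.binomial_group_mask(masks[c]).n_pixels > 0}
    zero = cfg.zero_label
    perm_sig = set()
    for ci, cond in enumerate(conditions):
        if cond == zero:
            continue
        rng = np.random.default_rng(np.random.SeedSequence([seed, 99, ci]))
        res = ss.permutation_condition_test(
            np.concatenate(pooled[cond]), np.concatenate(pooled[zero]), rng=rng)
        if res.significant:
            perm_sig.add(cond)
    return ss.classify_pair_window(nonzero, perm_sig, zero, conditions,
                                   pair=COUPLED_PAIR, band=ALPHA_BAND, window=COUPLING_WINDOW)


def subject_sr_curve(cfg: ss.SimConfig, subject_seed: int, source: str = "R_STG",
                     window: ss.WindowSpec | None = None) -> ss.SRCurve:
    """One subject's normalized power-ratio curve across all conditions."""
    if window is None:
        window = ss.WindowSpec(0.0, 0.100, 30.0, 50.0, "40-Hz response")
    grid = ss.make_frequency_grid(srate=cfg.srate)
    raw = []
    for ci, cond in enumerate(cfg.conditions):
        rng = np.random.default_rng(np.random.SeedSequence([subject_seed, ci]))
        ep = ss.generate_source_epochs(cfg, f"S{subject_seed}", source, cond, rng)
        emap = ss.ersp(ss.morlet_tf(ep, grid))
        raw.append(ss.window_power_ratio(emap, window))
    return ss.normalize_curve(cfg.conditions, raw, subject=f"S{subject_seed}", source=source)
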