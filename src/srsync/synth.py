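"""Synthetic source-level EEG with noise-modulated phase resetting.

The generator emulates the statistical structure that the downstream analysis
assumes about independent-component (IC) activations recorded during a
near-threshold auditory task with added broadband noise:

* Each cortical source carries ongoing, random-phase gamma activity (default
  40 Hz) produced by a finite population of unit oscillators riding on 1/f
  background noise.  At stimulus onset every oscillator's phase relaxes
  (exponentially, default time constant 25 ms) toward a target drawn from a
  von Mises distribution centred on a stimulus-locked phase.  The von Mises
  concentration ``kappa`` controls how completely the population synchronizes:
  alignment of the population raises the amplitude of the aggregate signal,
  which is what baseline-normalized spectral power (ERSP) measures, and also
  raises inter-trial phase coherence.
* ``kappa`` depends on the acoustic noise level through an inverted-U
  stochastic-resonance profile: weak noise helps the near-threshold stimulus
  reset the population, strong noise destroys the reset.
* Pairs of sources can additionally share band-limited oscillations whose
  per-trial phase difference is von Mises distributed inside a configured
  time-frequency window — noise-modulated inter-regional phase coupling.

All randomness flows through :class:`numpy.random.Generator` objects derived
from the configured seed, so identical configurations reproduce bit-identical
epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidConfigError
from .windows import BASELINE_WINDOW, RESPONSE_WINDOW

__all__ = [
    "SRProfileParams",
    "SimConfig",
    "EpochSet",
    "sr_profile",
    "noise_amplitude",
    "generate_source_epochs",
    "generate_coupled_pair",
    "generate_dataset",
    "default_config",
]

ZERO_LABEL = "none"

DEFAULT_SOURCES = ("R_STG", "L_STG", "L_SFG", "L_PCi")
DEFAULT_CONDITIONS = ("none", "-5", "0", "5", "10", "20")


@dataclass(frozen=True)
class SRProfileParams:
    """Parameters of the inverted-U noise -> concentration profile.

    ``kappa(sigma) = kappa0 + kappa_sr * (sigma/sigma_opt)**2
    * exp(1 - (sigma/sigma_opt)**2)`` — equal to ``kappa0`` at zero noise,
    maximal (``kappa0 + kappa_sr``) at ``sigma_opt``, and decaying back to
    ``kappa0`` for large noise.
    """

    kappa0: float
    kappa_sr: float
    sigma_opt: float

    def __post_init__(self) -> None:
        if self.kappa0 < 0 or self.kappa_sr < 0:
            raise InvalidConfigError("kappa0 and kappa_sr must be >= 0")
        if not (self.sigma_opt > 0):
            raise InvalidConfigError("sigma_opt must be > 0")


def sr_profile(sigma: float, params: SRProfileParams) -> float:
    """Von Mises concentration at noise amplitude ``sigma``.

    Smooth with a single interior maximum at ``sigma == sigma_opt`` where it
    equals ``kappa0 + kappa_sr``.
    """
    if sigma < 0:
        raise InvalidConfigError(f"noise amplitude must be >= 0, got {sigma}")
    x = sigma / params.sigma_opt
    return params.kappa0 + params.kappa_sr * x**2 * math.exp(1.0 - x**2)


def noise_amplitude(condition: str, noise_map_scale: float, zero_label: str = ZERO_LABEL) -> float:
    """Map a noise-condition label to a linear noise amplitude.

    The zero-noise label maps to exactly 0; a dB(SL) label ``d`` maps to
    ``noise_map_scale * 10**(d/20)``.
    """
    if condition == zero_label:
        return 0.0
    try:
        level_db = float(condition)
    except (TypeError, ValueError):
        raise KeyError(f"unknown noise condition label: {condition!r}") from None
    return noise_map_scale * 10.0 ** (level_db / 20.0)


@dataclass(frozen=True)
class EpochSet:
    """Trials x samples of one {subject, source, condition} recording."""

    data: np.ndarray
    srate: float
    t_start: float
    subject: str
    source: str
    condition: str
    ear: str = "left"
    units: str = "a.u."

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 2:
            raise InvalidConfigError("epoch data must be a (trials, samples) matrix")
        if not (self.srate > 0) or not np.isfinite(self.srate):
            raise InvalidConfigError("srate must be positive and finite")
        t_end = self.t_start + (data.shape[1] - 1) / self.srate
        if not (self.t_start < 0.0 < t_end):
            raise InvalidConfigError(
                f"stimulus onset must lie strictly inside the epoch "
                f"[{self.t_start}, {t_end}]"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.srate


# --- coupling specification -------------------------------------------------

@dataclass(frozen=True)
class CouplingSpec:
    """Phase coupling between one source pair in one (band, window) cell."""

    pair: tuple[str, str]
    band: tuple[float, float]       # Hz
    window: tuple[float, float]     # s
    params: SRProfileParams


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic study.

    Defaults mirror the emulated study: 10 subjects, four sources (bilateral
    superior temporal gyri, left superior frontal gyrus, left posterior
    cingulate), six noise conditions (no-noise plus -5..20 dB SL), 250 Hz
    sampling, epochs -150..+450 ms around onset, 40-Hz target oscillation.
    Trial counts are reduced from the study's ~950/condition to 100 for desk
    scale.
    """

    n_subjects: int = 10
    sources: tuple[str, ...] = DEFAULT_SOURCES
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_trials: int = 100
    srate: float = 250.0
    epoch_window: tuple[float, float] = (-0.150, 0.450)
    f0: float = 40.0
    a_osc: float = 1.0
    a_bg: float = 0.5
    n_oscillators: int = 50
    tau_reset: float = 0.025
    reset_params: dict = field(
        default_factory=lambda: {s: SRProfileParams(0.2, 2.5, 1.0) for s in DEFAULT_SOURCES}
    )
    coupling: tuple[CouplingSpec, ...] = field(
        default_factory=lambda: (
            CouplingSpec(("R_STG", "L_SFG"), (9.0, 14.0), (0.05, 0.30), SRProfileParams(0.0, 4.0, 1.0)),
        )
    )
    noise_map_scale: float = 1.0
    ear: str = "left"
    zero_label: str = ZERO_LABEL
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise InvalidConfigError("condition labels must be unique")
        zeros = [c for c in self.conditions
                 if noise_amplitude(c, self.noise_map_scale, self.zero_label) == 0.0]
        if len(zeros) != 1:
            raise InvalidConfigError(
                f"conditions must contain exactly one zero-noise label, found {zeros}"
            )
        t0, t1 = self.epoch_window
        if not (t0 <= BASELINE_WINDOW[0] and BASELINE_WINDOW[1] <= t1):
            raise InvalidConfigError("epoch window must contain the baseline window")
        if not (t0 <= RESPONSE_WINDOW[0] and RESPONSE_WINDOW[1] <= t1):
            raise InvalidConfigError("epoch window must contain the response window")
        for v, name in ((self.a_osc, "a_osc"), (self.a_bg, "a_bg")):
            if not np.isfinite(v):
                raise InvalidConfigError(f"{name} must be finite")
        if not (self.srate > 0):
            raise InvalidConfigError("srate must be > 0")
        if self.n_trials < 1 or self.n_subjects < 1 or self.n_oscillators < 1:
            raise InvalidConfigError("counts must be >= 1")
        self._check_coupling_overlap()

    def _check_coupling_overlap(self) -> None:
        """Reject two coupling specs claiming the same source in overlapping
        (band x window) pixel regions — their phase prescriptions would clash."""
        specs = list(self.coupling)
        for i in range(len(specs)):
            for j in range(i + 1, len(specs)):
                a, b = specs[i], specs[j]
                shared = set(a.pair) & set(b.pair)
                if not shared:
                    continue
                band_olap = a.band[0] < b.band[1] and b.band[0] < a.band[1]
                win_olap = a.window[0] < b.window[1] and b.window[0] < a.window[1]
                if band_olap and win_olap:
                    raise InvalidConfigError(
                        f"contradictory coupling specs for source(s) {sorted(shared)} "
                        f"in overlapping band/window: {a.pair}/{a.band} vs {b.pair}/{b.band}"
                    )

    def reset_params_for(self, source: str) -> SRProfileParams:
        try:
            return self.reset_params[source]
        except KeyError:
            raise InvalidConfigError(f"no reset parameters for source {source!r}") from None

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_window
        return int(round((t1 - t0) * self.srate))

    @property
    def times(self) -> np.ndarray:
        return self.epoch_window[0] + np.arange(self.n_samples) / self.srate


def default_config(**overrides) -> SimConfig:
    """The study's default configuration with keyword overrides."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()


# --- primitive signal components ---------------------------------------------

def pink_noise(rng: np.random.Generator, n_trials: int, n_samples: int, srate: float) -> np.ndarray:
    """Unit-variance (in expectation) 1/f-power noise band-limited to 1-100 Hz.

    Gaussian white noise is shaped in the frequency domain with amplitude
    ``f**-0.5`` inside 1-100 Hz and zero outside, then rescaled by the exact
    expected standard deviation of the shaped process.  The deterministic
    rescaling keeps the process Gaussian and stationary.
    """
    white = rng.standard_normal((n_trials, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    amp = np.zeros_like(freqs)
    band = (freqs >= 1.0) & (freqs <= 100.0)
    amp[band] = freqs[band] ** -0.5
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * amp, n=n_samples, axis=1)
    # E[var] of the shaped process given unit-variance white input:
    weights = np.full_like(amp, 2.0)
    weights[0] = 1.0
    if n_samples % 2 == 0:
        weights[-1] = 1.0
    expected_var = float(np.sum(weights * amp**2)) / n_samples
    return shaped / np.sqrt(expected_var)


def _wrap(angle: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * angle))


def _relax(start: np.ndarray, target: np.ndarray, dt: np.ndarray, tau: float) -> np.ndarray:
    """Wrap-aware exponential phase relaxation from ``start`` toward ``target``.

    ``start``/``target`` broadcast against each other; ``dt`` is time since the
    relaxation began (>= 0), broadcast on a trailing axis.
    """
    delta = _wrap(start - target)
    return target + delta * np.exp(-dt / tau)


# --- generators ---------------------------------------------------------------

def generate_source_epochs(
    config: SimConfig,
    subject: str,
    source: str,
    condition: str,
    rng: np.random.Generator,
) -> EpochSet:
    """One source's epochs for one noise condition.

    Per trial the signal is ``a_bg * pink + a_osc * mean_m cos(2 pi f0 t +
    phi_m(t))`` over ``n_oscillators`` population members ``m``.  Pre-stimulus
    phase offsets are independent Uniform(-pi, pi]; for ``t >= 0`` each
    offset relaxes exponentially (``tau_reset``) toward a target drawn from
    von Mises(0, kappa) with ``kappa = sr_profile(noise_amplitude(condition))``
    for this source.  With ``kappa -> inf`` the whole population aligns on the
    stimulus-locked phase in every trial.
    """
    sigma = noise_amplitude(condition, config.noise_map_scale, config.zero_label)
    kappa = sr_profile(sigma, config.reset_params_for(source))
    n, s, m = config.n_trials, config.n_samples, config.n_oscillators
    times = config.times

    bg = config.a_bg * pink_noise(rng, n, s, config.srate)

    theta = rng.uniform(-np.pi, np.pi, size=(n, m))          # pre-stimulus offsets
    if kappa > 0:
        psi = rng.vonmises(0.0, kappa, size=(n, m))          # reset targets
    else:
        psi = rng.uniform(-np.pi, np.pi, size=(n, m))        # kappa=0: uniform
    post = times >= 0.0
    # offsets: (trials, oscillators, samples)
    phi = np.broadcast_to(theta[:, :, None], (n, m, s)).copy()
    phi[:, :, post] = _relax(theta[:, :, None], psi[:, :, None],
                             times[post][None, None, :], config.tau_reset)
    carrier = 2.0 * np.pi * config.f0 * times
    osc = np.cos(carrier[None, None, :] + phi).mean(axis=1)

    data = bg + config.a_osc * osc
    return EpochSet(data, config.srate, config.epoch_window[0],
                    subject=subject, source=source, condition=condition, ear=config.ear)


def _coupled_components(
    config: SimConfig,
    spec: CouplingSpec,
    condition: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Band-limited oscillation pair (trials x samples each) whose phase
    difference inside ``spec.window`` is von Mises(0, lambda) per trial and
    whose phases are independent outside it.

    The window's phase prescription is entered and left through a short
    wrap-aware exponential relaxation (10 ms) so the instantaneous phase stays
    continuous.
    """
    sigma = noise_amplitude(condition, config.noise_map_scale, config.zero_label)
    lam = sr_profile(sigma, spec.params)
    n, s = config.n_trials, config.n_samples
    times = config.times
    f_c = math.sqrt(spec.band[0] * spec.band[1])
    t0, t1 = spec.window
    tau_c = 0.010

    theta = rng.uniform(-np.pi, np.pi, size=(n, 1))          # source i, constant offset
    eta = rng.uniform(-np.pi, np.pi, size=(n, 1))            # source j, free pre-window
    eta2 = rng.uniform(-np.pi, np.pi, size=(n, 1))           # source j, free post-window
    if lam > 0:
        delta = rng.vonmises(0.0, lam, size=(n, 1))
    else:
        delta = rng.uniform(-np.pi, np.pi, size=(n, 1))
    target = theta + delta

    offset_j = np.broadcast_to(eta, (n, s)).copy()
    inside = (times >= t0) & (times <= t1)
    after = times > t1
    offset_j[:, inside] = _relax(eta, target, (times[inside] - t0)[None, :], tau_c)
    # value reached at the window end, then relax back to an independent phase
    v_end = _relax(eta, target, np.array([t1 - t0]), tau_c)
    offset_j[:, after] = _relax(v_end, eta2, (times[after] - t1)[None, :], tau_c)

    carrier = 2.0 * np.pi * f_c * times[None, :]
    x_i = np.cos(carrier + theta)
    x_j = np.cos(carrier + offset_j)
    return x_i, x_j


def generate_coupled_pair(
    config: SimConfig,
    pair: tuple[str, str],
    condition: str,
    band: tuple[float, float],
    window: tuple[float, float],
    rng: np.random.Generator,
    params: SRProfileParams | None = None,
) -> tuple[EpochSet, EpochSet]:
    """Two sources sharing noise-modulated phase coupling in one band/window.

    Each source is 1/f background plus a band-centre oscillation; within
    ``window`` the pair's per-trial phase difference is von Mises(0, lambda)
    with ``lambda = sr_profile(noise_amplitude(condition), params)``; outside
    it the phases are independent.  Both members get equal trial counts with
    aligned trial indices.
    """
    if not (5.0 <= band[0] < band[1] <= 55.0):
        raise InvalidConfigError(f"coupling band must lie within 5-55 Hz, got {band}")
    t0, t1 = window
    e0, e1 = config.epoch_window
    if not (e0 <= t0 < t1 <= e1):
        raise InvalidConfigError(f"coupling window {window} outside epoch {config.epoch_window}")
    if params is None:
        matches = [sp for sp in config.coupling
                   if set(sp.pair) == set(pair) and sp.band == tuple(band) and sp.window == tuple(window)]
        if not matches:
            raise InvalidConfigError(f"no coupling parameters configured for {pair}/{band}/{window}")
        params = matches[0].params
    spec = CouplingSpec(tuple(pair), tuple(band), tuple(window), params)

    n, s = config.n_trials, config.n_samples
    bg_i = config.a_bg * pink_noise(rng, n, s, config.srate)
    bg_j = config.a_bg * pink_noise(rng, n, s, config.srate)
    x_i, x_j = _coupled_components(config, spec, condition, rng)
    kw = dict(srate=config.srate, t_start=e0, subject="sim", condition=condition, ear=config.ear)
    ep_i = EpochSet(bg_i + config.a_osc * x_i, source=pair[0], **kw)
    ep_j = EpochSet(bg_j + config.a_osc * x_j, source=pair[1], **kw)
    return ep_i, ep_j


def _rng_for(config: SimConfig, *key: int) -> np.random.Generator:
    """Deterministic per-cell generator derived from the config seed."""
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *map(int, key)]))


def subject_ids(config: SimConfig) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(config.n_subjects)]


def generate_dataset(config: SimConfig) -> list[EpochSet]:
    """Full study: per subject x source x condition epochs.

    Every source carries the 40-Hz phase-reset dynamics; coupling specs add
    their band-limited coupled components on top of the two member sources.
    Reproducible bit-for-bit for a fixed config (incl. seed).
    """
    epochs: dict[tuple[str, str, str], EpochSet] = {}
    subjects = subject_ids(config)
    for si, subject in enumerate(subjects):
        for soi, source in enumerate(config.sources):
            for ci, condition in enumerate(config.conditions):
                rng = _rng_for(config, 0, si, soi, ci)
                epochs[(subject, source, condition)] = generate_source_epochs(
                    config, subject, source, condition, rng
                )
        for ki, spec in enumerate(config.coupling):
            src_i, src_j = spec.pair
            if src_i not in config.sources or src_j not in config.sources:
                raise InvalidConfigError(f"coupling pair {spec.pair} not in sources")
            for ci, condition in enumerate(config.conditions):
                rng = _rng_for(config, 1, si, ki, ci)
                x_i, x_j = _coupled_components(config, spec, condition, rng)
                for src, comp in ((src_i, x_i), (src_j, x_j)):
                    ep = epochs[(subject, src, condition)]
                    epochs[(subject, src, condition)] = replace(
                        ep, data=ep.data + config.a_osc * comp
                    )
    return list(epochs.values())
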