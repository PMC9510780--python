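"""Synthetic two-channel ECoG cohorts with known ground-truth anesthetic depth.

Real epidural recordings under a stepped isoflurane protocol are emulated by a
generative model with four depth-modulated ingredients:

* a shared band-limited (5-40 Hz) stochastic oscillation entering both
  channels with a depth-dependent mixing weight, which sets the
  interhemispheric magnitude-squared coherence;
* a two-state (burst/suppression) renewal process whose mean suppression
  duration grows with depth, gating the oscillatory and broadband components;
* independent per-channel 1/f-shaped background noise plus 50 Hz mains
  contamination (the mains line is never gated);
* stimulus-evoked responses at whisker-stimulus onsets whose amplitude is
  attenuated linearly in depth.

The hidden depth ``d`` in [0, 1] is a monotone (linear, clipped) map of the
administered isoflurane concentration, optionally low-pass smoothed to mimic
gradual uptake at segment transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "AnesthesiaProtocol",
    "GeneratorConfig",
    "Recording",
    "make_protocol",
    "raised_cosine_pulse",
    "make_stimulus_train",
    "simulate_recording",
    "simulate_cohort",
    "STEPPED_PROTOCOL_PERCENT",
]

#: The stepped isoflurane maintenance schedule used throughout: seven
#: consecutive segments at these percent concentrations.
STEPPED_PROTOCOL_PERCENT = (1.5, 2.3, 1.0, 1.5, 1.0, 2.3, 1.5)


@dataclass(frozen=True)
class AnesthesiaProtocol:
    """Piecewise-constant isoflurane schedule: (percent, duration_s) segments."""

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for conc, dur in self.segments:
            if conc <= 0 or dur <= 0:
                raise ValueError("concentrations and durations must be positive")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.segments))

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(c for c, _ in self.segments)

    def boundaries_s(self) -> np.ndarray:
        """Segment start/end times: length ``len(segments)+1``, starts at 0."""
        return np.concatenate([[0.0], np.cumsum([d for _, d in self.segments])])

    def concentration_at(self, t: np.ndarray) -> np.ndarray:
        """Administered concentration (percent) at times ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        edges = self.boundaries_s()
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(self.segments) - 1)
        conc = np.array([c for c, _ in self.segments])
        return conc[idx]


def make_protocol(
    concentrations: Sequence[float], segment_minutes: float
) -> AnesthesiaProtocol:
    """Build an equal-segment-length protocol from a concentration sequence."""
    if len(concentrations) == 0:
        raise ValueError("need at least one concentration")
    if segment_minutes <= 0:
        raise ValueError("segment_minutes must be positive")
    dur = float(segment_minutes) * 60.0
    return AnesthesiaProtocol(tuple((float(c), dur) for c in concentrations))


def raised_cosine_pulse(
    amplitude_um: float, frequency_hz: float, sample_rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """One full cycle of a raised-cosine displacement pulse.

    x(t) = A/2 * (1 - cos(2*pi*f*t)) for t in [0, 1/f]; starts and ends at
    zero displacement with peak ``amplitude_um``. Returns ``(t_s, x_um)``.
    The analytic peak velocity is ``A*pi*f`` (e.g. 300 um at 120 Hz gives
    113.1 mm/s over an 8.3 ms pulse).
    """
    if amplitude_um < 0 or frequency_hz <= 0 or sample_rate_hz <= 0:
        raise ValueError("amplitude must be >= 0 and rates positive")
    if sample_rate_hz <= 2 * frequency_hz:
        raise ValueError("sample_rate must exceed twice the pulse frequency")
    n = int(round(sample_rate_hz / frequency_hz))
    t = np.arange(n + 1) / sample_rate_hz
    x = amplitude_um / 2.0 * (1.0 - np.cos(2.0 * np.pi * frequency_hz * t))
    return t, x


def make_stimulus_train(
    total_duration_s: float,
    pulse_rate_hz: float = 1.0,
    on_period_s: float = 2.0,
    off_period_s: float = 2.0,
) -> np.ndarray:
    """Stimulus onset times for a pulse train gated by on/off periods.

    Pulses at ``pulse_rate_hz`` spacing inside alternating stimulus-on windows
    of ``on_period_s``; no pulses during the interleaved off windows.
    """
    if total_duration_s < 0 or pulse_rate_hz <= 0 or on_period_s <= 0 or off_period_s <= 0:
        raise ValueError("arguments must be positive (duration >= 0)")
    if on_period_s < 1.0 / pulse_rate_hz:
        raise ValueError("on period shorter than one pulse interval")
    onsets = []
    cycle = on_period_s + off_period_s
    t0 = 0.0
    while t0 < total_duration_s:
        k = 0
        while True:
            t = t0 + k / pulse_rate_hz
            if t >= t0 + on_period_s or t >= total_duration_s:
                break
            onsets.append(t)
            k += 1
        t0 += cycle
    return np.array(onsets, dtype=float)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic ECoG generator.

    Depth ``d`` is ``clip((c - depth_c_lo) / (depth_c_hi - depth_c_lo), 0, 1)``
    for administered concentration ``c`` (percent). Modulation toggles exist so
    individual mechanisms can be isolated in experiments (e.g. coherence-only
    cohorts for importance-recovery checks).
    """

    sample_rate: float = 250.0
    seed: int = 0
    # hidden-depth map and transition smoothing
    depth_c_lo: float = 0.8
    depth_c_hi: float = 2.5
    depth_tau_s: float = 60.0  # 0 disables the first-order transition
    # shared oscillation / coherence
    osc_band_hz: tuple[float, float] = (5.0, 40.0)
    osc_rms_uv: float = 30.0
    rho_min: float = 0.15
    rho_max: float = 0.85
    modulate_coherence: bool = True
    # depth-dependent slow-wave (delta) component: anesthetic spectral slowing
    slow_band_hz: tuple[float, float] = (0.5, 3.0)
    slow_rms_max_uv: float = 60.0
    modulate_slow: bool = True
    # burst suppression (alternating exponential on/off renewal)
    burst_mean_on_s: float = 3.0
    burst_mean_off_max_s: float = 6.0
    suppression_gain: float = 0.05
    suppression_slow_residual_uv: float = 8.0
    modulate_bursts: bool = True
    # background noise
    aperiodic_exponent: float = 2.0
    noise_rms_uv: float = 15.0
    # mains contamination
    line_noise_amplitude_uv: float = 10.0
    line_hz: float = 50.0
    # evoked responses
    evoked_amplitude_uv: float = 120.0
    evoked_latency_s: float = 0.025
    evoked_width_s: float = 0.040
    evoked_attenuation: float = 0.6
    evoked_ipsi_fraction: float = 0.4
    modulate_evoked: bool = True
    # stimulus train
    stim_enabled: bool = True
    stim_pulse_rate_hz: float = 1.0
    stim_on_s: float = 2.0
    stim_off_s: float = 2.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 2 * 45.0:
            raise ValueError("sample_rate must exceed twice the 45 Hz analysis cap")
        if not (0.0 <= self.rho_min <= self.rho_max < 1.0):
            raise ValueError("require 0 <= rho_min <= rho_max < 1")
        if self.burst_mean_off_max_s < 0 or self.burst_mean_on_s <= 0:
            raise ValueError("burst durations must be positive (off max >= 0)")
        if self.depth_c_hi <= self.depth_c_lo:
            raise ValueError("depth_c_hi must exceed depth_c_lo")

    def depth_from_concentration(self, c: np.ndarray) -> np.ndarray:
        d = (np.asarray(c, dtype=float) - self.depth_c_lo) / (
            self.depth_c_hi - self.depth_c_lo
        )
        return np.clip(d, 0.0, 1.0)

    def rho(self, d: np.ndarray) -> np.ndarray:
        """Coherence mixing weight as a nondecreasing function of depth."""
        if not self.modulate_coherence:
            return np.full_like(np.asarray(d, dtype=float), self.rho_min)
        return self.rho_min + (self.rho_max - self.rho_min) * np.asarray(d, dtype=float)

    def mean_off_s(self, d: float) -> float:
        """Mean suppression-interval duration at depth ``d``."""
        if not self.modulate_bursts:
            return 0.0
        return self.burst_mean_off_max_s * float(d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Recording:
    """Two-channel ECoG trace with stimulus onsets and protocol metadata.

    ``ground_truth_depth`` (per-sample hidden depth in [0, 1]) exists only for
    synthetic recordings and is never exposed to the estimator.
    """

    channel_contra: np.ndarray
    channel_ipsi: np.ndarray
    sample_rate: float
    stim_onsets: np.ndarray
    protocol: AnesthesiaProtocol
    animal_id: str = "m00"
    ground_truth_depth: np.ndarray | None = None
    input_referred: bool = True

    def __post_init__(self) -> None:
        self.channel_contra = np.asarray(self.channel_contra, dtype=float)
        self.channel_ipsi = np.asarray(self.channel_ipsi, dtype=float)
        self.stim_onsets = np.asarray(self.stim_onsets, dtype=float)
        if self.channel_contra.shape != self.channel_ipsi.shape:
            raise ValueError("channels must have equal length")
        if self.stim_onsets.size and (
            np.any(np.diff(self.stim_onsets) <= 0)
            or self.stim_onsets[-1] > self.duration_s
            or self.stim_onsets[0] < 0
        ):
            raise ValueError("stim onsets must be strictly increasing within duration")

    @property
    def n_samples(self) -> int:
        return self.channel_contra.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channels(self) -> dict[str, np.ndarray]:
        return {"contra": self.channel_contra, "ipsi": self.channel_ipsi}


def _smooth_depth(d: np.ndarray, fs: float, tau_s: float) -> np.ndarray:
    """First-order exponential approach to the commanded depth trace."""
    if tau_s <= 0:
        return d
    alpha = 1.0 / (fs * tau_s)
    alpha = min(alpha, 1.0)
    b, a = [alpha], [1.0, alpha - 1.0]
    zi = signal.lfiltic(b, a, [d[0]], [d[0]])
    out, _ = signal.lfilter(b, a, d, zi=zi)
    return out


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ f**(-exponent)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shaping, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _bandlimited_source(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance white noise band-passed to ``band``."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _burst_gate(
    rng: np.random.Generator, depth: np.ndarray, fs: float, cfg: GeneratorConfig
) -> np.ndarray:
    """Amplitude gate from an alternating exponential on/off renewal process.

    Off (suppression) intervals scale the gated components to
    ``suppression_gain``; the mean off duration is evaluated at the depth
    prevailing when each suppression interval starts.
    """
    n = depth.size
    gate = np.ones(n)
    i = 0
    state_on = True
    while i < n:
        if state_on:
            dur = rng.exponential(cfg.burst_mean_on_s)
        else:
            mean_off = cfg.mean_off_s(depth[i])
            if mean_off <= 0:
                state_on = True
                continue
            dur = rng.exponential(mean_off)
        j = min(n, i + max(1, int(round(dur * fs))))
        if not state_on:
            gate[i:j] = cfg.suppression_gain
        i = j
        state_on = not state_on
    return gate


def _evoked_kernel(fs: float, latency_s: float, width_s: float) -> np.ndarray:
    """Unit-peak damped half-sine response, delayed by ``latency_s``."""
    n_lat = int(round(latency_s * fs))
    n_w = max(2, int(round(width_s * fs)))
    t = np.arange(n_w) / n_w
    k = np.sin(np.pi * t) * np.exp(-2.0 * t)
    k /= np.abs(k).max()
    return np.concatenate([np.zeros(n_lat), k])


def simulate_recording(
    config: GeneratorConfig,
    protocol: AnesthesiaProtocol,
    animal_id: str = "m00",
    seed: int | None = None,
) -> Recording:
    """Simulate one animal's two-channel recording under ``protocol``.

    Deterministic given ``(config, protocol, seed)``; ``seed`` defaults to
    ``config.seed``.
    """
    fs = config.sample_rate
    n = int(round(protocol.total_duration_s * fs))
    rng = np.random.default_rng(config.seed if seed is None else seed)

    t = np.arange(n) / fs
    conc = protocol.concentration_at(t)
    depth = _smooth_depth(config.depth_from_concentration(conc), fs, config.depth_tau_s)

    shared = _bandlimited_source(rng, n, fs, config.osc_band_hz)
    indep_c = _bandlimited_source(rng, n, fs, config.osc_band_hz)
    indep_i = _bandlimited_source(rng, n, fs, config.osc_band_hz)
    rho = config.rho(depth)
    w_sh, w_in = np.sqrt(rho), np.sqrt(1.0 - rho)
    osc_c = config.osc_rms_uv * (w_sh * shared + w_in * indep_c)
    osc_i = config.osc_rms_uv * (w_sh * shared + w_in * indep_i)

    noise_c = config.noise_rms_uv * _pink_noise(rng, n, fs, config.aperiodic_exponent)
    noise_i = config.noise_rms_uv * _pink_noise(rng, n, fs, config.aperiodic_exponent)

    gate = _burst_gate(rng, depth, fs, config)

    # Anesthetic spectral slowing: per-channel delta-band waves growing with
    # depth (lower median-crossing rate and template irregularity). During
    # suppression the fast components are quenched to ``suppression_gain``
    # while a small slow residual persists (suppression is quasi-isoelectric,
    # not a scaled replica of the burst signal).
    slow_amp = config.slow_rms_max_uv * depth if config.modulate_slow else np.zeros(n)
    off = gate < 1.0
    slow_scale = np.where(
        off, np.maximum(config.suppression_slow_residual_uv, gate * slow_amp), slow_amp
    )
    if np.any(slow_scale > 0):
        slow_c = slow_scale * _bandlimited_source(rng, n, fs, config.slow_band_hz)
        slow_i = slow_scale * _bandlimited_source(rng, n, fs, config.slow_band_hz)
    else:
        slow_c = slow_i = 0.0

    line = config.line_noise_amplitude_uv * np.sin(2.0 * np.pi * config.line_hz * t)

    ch_c = gate * (osc_c + noise_c) + slow_c + line
    ch_i = gate * (osc_i + noise_i) + slow_i + line

    if config.stim_enabled:
        onsets = make_stimulus_train(
            protocol.total_duration_s,
            config.stim_pulse_rate_hz,
            config.stim_on_s,
            config.stim_off_s,
        )
        kernel = _evoked_kernel(fs, config.evoked_latency_s, config.evoked_width_s)
        for onset in onsets:
            i0 = int(round(onset * fs))
            j = min(n, i0 + kernel.size)
            if j <= i0:
                continue
            atten = config.evoked_attenuation * depth[i0] if config.modulate_evoked else 0.0
            amp = config.evoked_amplitude_uv * max(0.0, 1.0 - atten)
            ch_c[i0:j] += amp * kernel[: j - i0]
            ch_i[i0:j] += config.evoked_ipsi_fraction * amp * kernel[: j - i0]
    else:
        onsets = np.empty(0)

    return Recording(
        channel_contra=ch_c,
        channel_ipsi=ch_i,
        sample_rate=fs,
        stim_onsets=onsets,
        protocol=protocol,
        animal_id=animal_id,
        ground_truth_depth=depth,
    )


def simulate_cohort(
    n_animals: int,
    config: GeneratorConfig,
    protocol: AnesthesiaProtocol,
    seed: int | None = None,
) -> list[Recording]:
    """Simulate ``n_animals`` independent recordings under a shared protocol.

    Per-animal streams are spawned from one root seed so cohorts are
    reproducible as a whole and animals are statistically independent.
    """
    if n_animals < 1:
        raise ValueError("need at least one animal")
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    children = root.spawn(n_animals)
    recs = []
    for k, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        recs.append(
            simulate_recording(config, protocol, animal_id=f"m{k:02d}", seed=child_seed)
        )
    return recs
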