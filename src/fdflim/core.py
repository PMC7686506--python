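"""Frequency-domain (homodyne) FLIM mathematics.

In frequency-domain fluorescence lifetime imaging the excitation laser
intensity is sinusoidally modulated at a frequency ``f``.  The fluorescence
returns at the same frequency but phase-shifted by ``phi = arctan(omega * tau)``
and demodulated by ``m = 1 / sqrt(1 + (omega * tau)^2)`` for a mono-exponential
decay with lifetime ``tau`` (``omega = 2 * pi * f``).  A homodyne camera samples
the detected sinusoid at ``K`` equally spaced phase offsets; a discrete Fourier
estimator recovers phase, modulation depth and DC level per pixel, and a
reference target of known lifetime removes the instrument's own phase offset
and modulation gain.

This module provides the forward model (:func:`simulate_frames`), the
demodulation and calibration steps, lifetime conversions, and phasor algebra
for multi-exponential decay mixtures.  Lifetimes are expressed in nanoseconds
and frequencies in Hz throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Channel",
    "ModulationConfig",
    "RawFrameStack",
    "DemodulationResult",
    "CalibrationReference",
    "LifetimeMap",
    "DecayModel",
    "Phasor",
    "CalibrationError",
    "simulate_frames",
    "synthesize_stack",
    "demodulate",
    "calibrate",
    "phase_lifetime",
    "modulation_lifetime",
    "lifetime_to_phasor",
    "mixture_phasor",
    "apparent_phase_lifetime",
    "solve_long_fraction",
    "map_from_demodulation",
    "reconstruct_map",
]

NS_PER_S = 1e9


class Channel(str, enum.Enum):
    """Fluorescence detection channel."""

    NADH = "NADH"
    PPIX = "PPIX"


class CalibrationError(ValueError):
    """Raised when a reference measurement cannot calibrate the system."""


@dataclass(frozen=True)
class ModulationConfig:
    """Homodyne acquisition settings.

    Parameters
    ----------
    frequency_hz
        Laser modulation frequency ``f`` in Hz (default 10 MHz, optimal for
        lifetimes near ``1/(2*pi*f) = 15.9 ns``, i.e. the native PPIX decay).
    n_phase_steps
        Number ``K`` of equally spaced detector phase offsets (default 16).
    """

    frequency_hz: float = 10e6
    n_phase_steps: int = 16

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.n_phase_steps < 3:
            raise ValueError("need at least 3 phase steps to demodulate")

    @property
    def omega(self) -> float:
        """Angular modulation frequency ``2*pi*f`` (rad/s)."""
        return 2.0 * np.pi * self.frequency_hz

    @property
    def phase_offsets_rad(self) -> np.ndarray:
        """Detector phase offsets ``theta_k = 2*pi*k/K``, ``k = 0..K-1``."""
        k = self.n_phase_steps
        return 2.0 * np.pi * np.arange(k) / k


@dataclass
class RawFrameStack:
    """One channel's stack of ``K`` phase-stepped homodyne frames."""

    frames: np.ndarray  # (K, H, W) non-negative intensities
    config: ModulationConfig
    channel: Channel = Channel.PPIX
    exposure_ms: float = 100.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (K, H, W) array")
        if self.frames.shape[0] != self.config.n_phase_steps:
            raise ValueError(
                f"frame count {self.frames.shape[0]} != "
                f"n_phase_steps {self.config.n_phase_steps}"
            )
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class DemodulationResult:
    """Per-pixel phase delay, modulation depth and DC level."""

    phase_rad: np.ndarray  # wrapped to [0, 2*pi)
    modulation: np.ndarray
    dc: np.ndarray
    valid: np.ndarray  # False where dc == 0 (phase/modulation undefined)


@dataclass
class CalibrationReference:
    """Instrument phase offset and modulation gain from a reference target.

    The reference target has a known lifetime ``tau_ref``; comparing its
    measured mean phase and modulation with the theoretical values yields the
    instrument contribution that must be removed from every sample
    measurement.
    """

    known_lifetime_ns: float
    instrument_phase_rad: float
    instrument_modulation: float
    config: ModulationConfig = field(default_factory=ModulationConfig)

    def __post_init__(self) -> None:
        if self.known_lifetime_ns < 0:
            raise ValueError("known_lifetime_ns must be >= 0")
        if self.instrument_modulation <= 0:
            raise CalibrationError("instrument modulation must be positive")


@dataclass
class LifetimeMap:
    """Per-pixel phase lifetime in ns with a validity mask."""

    tau_ns: np.ndarray
    valid: np.ndarray
    channel: Channel
    dc: np.ndarray

    def __post_init__(self) -> None:
        if not (self.tau_ns.shape == self.valid.shape == self.dc.shape):
            raise ValueError("tau_ns, valid and dc must share a shape")
        if not np.all(np.isfinite(self.tau_ns[self.valid])):
            raise ValueError("tau_ns must be finite wherever valid")


@dataclass(frozen=True)
class DecayModel:
    """Multi-exponential decay: component lifetimes and intensity fractions.

    ``intensity_fractions`` are steady-state (intensity-weighted) fractions
    ``a_i`` with ``sum(a_i) == 1``; they weight the component phasors linearly.
    """

    component_lifetimes_ns: tuple[float, ...]
    intensity_fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        taus = tuple(float(t) for t in self.component_lifetimes_ns)
        fracs = tuple(float(a) for a in self.intensity_fractions)
        object.__setattr__(self, "component_lifetimes_ns", taus)
        object.__setattr__(self, "intensity_fractions", fracs)
        if len(taus) != len(fracs) or not taus:
            raise ValueError("need matching, non-empty lifetimes and fractions")
        if any(t <= 0 for t in taus):
            raise ValueError("component lifetimes must be positive")
        if any(a < 0 or a > 1 for a in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("fractions must lie in [0, 1] and sum to 1")

    @classmethod
    def mono(cls, tau_ns: float) -> "DecayModel":
        return cls((tau_ns,), (1.0,))

    @classmethod
    def biexponential(
        cls, tau_long_ns: float, tau_short_ns: float, long_fraction: float
    ) -> "DecayModel":
        """Two-component decay with intensity fraction ``alpha`` on the long one."""
        return cls((tau_long_ns, tau_short_ns), (long_fraction, 1.0 - long_fraction))


@dataclass(frozen=True)
class Phasor:
    """Point ``(g, s) = (m*cos(phi), m*sin(phi))`` at the modulation frequency.

    Mono-exponential decays lie on the universal semicircle
    ``(g - 1/2)^2 + s^2 = 1/4``; mixtures lie on chords inside it.
    """

    g: float
    s: float

    @property
    def modulation(self) -> float:
        return float(np.hypot(self.g, self.s))

    @property
    def phase_rad(self) -> float:
        return float(np.arctan2(self.s, self.g))


# ---------------------------------------------------------------------------
# Forward model


def synthesize_stack(
    g: np.ndarray,
    s: np.ndarray,
    dc: np.ndarray,
    config: ModulationConfig,
    *,
    instrument_phase_rad: float = 0.0,
    instrument_modulation: float = 1.0,
    noise: str = "none",
    rng: np.random.Generator | None = None,
    channel: Channel = Channel.PPIX,
    exposure_ms: float = 100.0,
) -> RawFrameStack:
    """Synthesize homodyne frames from per-pixel phasor fields.

    Frame ``k`` has expectation ``dc * (1 + m_tot * cos(theta_k - phi_tot))``
    where ``(g, s)`` is rotated by the instrument phase and scaled by the
    instrument modulation gain.  ``noise='poisson'`` draws each frame value
    from a Poisson distribution around its expectation.
    """
    if instrument_modulation <= 0:
        raise ValueError("instrument_modulation must be positive")
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    dc = np.broadcast_to(np.asarray(dc, dtype=float), g.shape)
    if np.any(dc < 0):
        raise ValueError("dc must be non-negative")

    cos_i, sin_i = np.cos(instrument_phase_rad), np.sin(instrument_phase_rad)
    g_tot = instrument_modulation * (g * cos_i - s * sin_i)
    s_tot = instrument_modulation * (g * sin_i + s * cos_i)

    theta = config.phase_offsets_rad.reshape((-1,) + (1,) * g.ndim)
    # dc * (1 + m*cos(theta - phi)) expanded via g_tot = m*cos(phi), s_tot = m*sin(phi)
    frames = dc * (1.0 + g_tot * np.cos(theta) + s_tot * np.sin(theta))
    frames = np.clip(frames, 0.0, None)
    if noise == "poisson":
        rng = np.random.default_rng() if rng is None else rng
        frames = rng.poisson(frames).astype(float)
    return RawFrameStack(frames, config, channel=channel, exposure_ms=exposure_ms)


def simulate_frames(
    decay: DecayModel,
    dc: float | np.ndarray,
    config: ModulationConfig,
    *,
    instrument_phase_rad: float = 0.0,
    instrument_modulation: float = 1.0,
    noise: str = "none",
    seed: int | np.random.Generator | None = None,
    shape: tuple[int, int] = (1, 1),
    channel: Channel = Channel.PPIX,
    exposure_ms: float = 100.0,
) -> RawFrameStack:
    """Simulate a homodyne frame stack for a spatially uniform decay model.

    ``dc`` may be a scalar (broadcast over ``shape``) or an image whose shape
    then defines the field of view.
    """
    dc_arr = np.asarray(dc, dtype=float)
    if dc_arr.ndim == 0:
        dc_arr = np.full(shape, float(dc_arr))
    ph = mixture_phasor(decay, config.frequency_hz)
    g = np.full(dc_arr.shape, ph.g)
    s = np.full(dc_arr.shape, ph.s)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return synthesize_stack(
        g,
        s,
        dc_arr,
        config,
        instrument_phase_rad=instrument_phase_rad,
        instrument_modulation=instrument_modulation,
        noise=noise,
        rng=rng,
        channel=channel,
        exposure_ms=exposure_ms,
    )


# ---------------------------------------------------------------------------
# Demodulation and calibration


def demodulate(stack: RawFrameStack) -> DemodulationResult:
    """Recover per-pixel phase, modulation depth and DC by DFT at the first harmonic.

    For equally spaced phase offsets the single-frequency DFT estimator is
    exact on noiseless sinusoids:

    ``C = (2/K) * sum_k I_k cos(theta_k)``, ``S = (2/K) * sum_k I_k sin(theta_k)``,
    ``dc = mean_k I_k``, ``phi = atan2(S, C)`` and ``m = sqrt(C^2 + S^2) / dc``.

    Pixels with ``dc == 0`` carry no signal; they are flagged invalid rather
    than raising.
    """
    theta = stack.config.phase_offsets_rad
    k = stack.config.n_phase_steps
    frames = stack.frames
    shape = (-1,) + (1,) * (frames.ndim - 1)
    cos_t = np.cos(theta).reshape(shape)
    sin_t = np.sin(theta).reshape(shape)
    c = (2.0 / k) * np.sum(frames * cos_t, axis=0)
    s = (2.0 / k) * np.sum(frames * sin_t, axis=0)
    dc = np.mean(frames, axis=0)
    valid = dc > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(valid, np.hypot(c, s) / np.where(valid, dc, 1.0), np.nan)
    phase = np.mod(np.arctan2(s, c), 2.0 * np.pi)
    phase = np.where(valid, phase, np.nan)
    return DemodulationResult(phase_rad=phase, modulation=m, dc=dc, valid=valid)


def _wrap_to_pi(phase: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.mod(np.asarray(phase) + np.pi, 2.0 * np.pi) - np.pi


def calibrate(
    reference: RawFrameStack,
    known_lifetime_ns: float,
    config: ModulationConfig | None = None,
) -> CalibrationReference:
    """Derive instrument phase offset and modulation gain from a reference target.

    The reference's theoretical phase is ``arctan(omega * tau_ref)`` and its
    theoretical modulation ``1 / sqrt(1 + (omega * tau_ref)^2)``; the global
    mean of the measured values in excess of these defines the instrument.
    """
    config = reference.config if config is None else config
    if config != reference.config:
        raise ValueError("reference stack and config disagree")
    demod = demodulate(reference)
    # a usable reference must actually be modulated; 1e-6 guards against
    # pure round-off AC on constant frames
    usable = demod.valid & (demod.modulation > 1e-6)
    if not np.any(usable):
        raise CalibrationError("reference target has zero modulation everywhere")
    omega_tau = config.omega * known_lifetime_ns / NS_PER_S
    # circular mean so wrapped phases near 0/2pi average correctly
    mean_phase = float(
        np.angle(np.mean(np.exp(1j * demod.phase_rad[usable])))
    )
    mean_mod = float(np.mean(demod.modulation[usable]))
    if mean_mod <= 0:
        raise CalibrationError("reference target has zero mean modulation")
    phi_inst = float(_wrap_to_pi(mean_phase - np.arctan(omega_tau)))
    m_inst = mean_mod * float(np.sqrt(1.0 + omega_tau**2))
    return CalibrationReference(
        known_lifetime_ns=known_lifetime_ns,
        instrument_phase_rad=phi_inst,
        instrument_modulation=m_inst,
        config=config,
    )


# ---------------------------------------------------------------------------
# Lifetime conversions


def phase_lifetime(phase_rad: np.ndarray | float, frequency_hz: float) -> np.ndarray:
    """Phase lifetime ``tau_phi = tan(phi) / (2*pi*f)`` in ns.

    Phases outside ``[0, pi/2)`` are unphysical for a fluorescence decay and
    return NaN (the tangent diverges at ``pi/2``; negative phases would imply
    the emission leads the excitation).
    """
    phase = np.asarray(phase_rad, dtype=float)
    omega = 2.0 * np.pi * frequency_hz
    ok = (phase >= 0) & (phase < np.pi / 2)
    with np.errstate(invalid="ignore"):
        tau = np.where(ok, np.tan(np.where(ok, phase, 0.0)) / omega * NS_PER_S, np.nan)
    return tau if tau.ndim else float(tau)


def modulation_lifetime(
    modulation: np.ndarray | float, frequency_hz: float
) -> np.ndarray:
    """Modulation lifetime ``tau_m = sqrt(1/m^2 - 1) / (2*pi*f)`` in ns.

    Exposed as a diagnostic only; the analysis pipeline uses the phase
    lifetime.  ``m > 1`` (super-modulation, a noise artifact) and ``m <= 0``
    yield NaN.
    """
    m = np.asarray(modulation, dtype=float)
    omega = 2.0 * np.pi * frequency_hz
    ok = (m > 0) & (m <= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(ok, np.sqrt(np.clip(1.0 / m**2 - 1.0, 0.0, None)) / omega * NS_PER_S, np.nan)
    return tau if tau.ndim else float(tau)


# ---------------------------------------------------------------------------
# Phasor algebra


def lifetime_to_phasor(tau_ns: float, frequency_hz: float) -> Phasor:
    """Phasor of a mono-exponential decay; lies exactly on the universal semicircle."""
    if tau_ns < 0:
        raise ValueError("tau_ns must be >= 0")
    wt = 2.0 * np.pi * frequency_hz * tau_ns / NS_PER_S
    denom = 1.0 + wt**2
    return Phasor(g=1.0 / denom, s=wt / denom)


def mixture_phasor(decay: DecayModel, frequency_hz: float) -> Phasor:
    """Intensity-fraction-weighted sum of component phasors.

    Phasor space is linear in intensity fractions, so an ``n``-component
    mixture lies in the convex hull of its component phasors (on the chord,
    for two components).
    """
    g = s = 0.0
    for tau, a in zip(decay.component_lifetimes_ns, decay.intensity_fractions):
        p = lifetime_to_phasor(tau, frequency_hz)
        g += a * p.g
        s += a * p.s
    return Phasor(g=g, s=s)


def apparent_phase_lifetime(decay: DecayModel, frequency_hz: float) -> float:
    """Phase lifetime an FD-FLIM system reports for a decay mixture.

    ``tau_app = (s/g) / omega`` of the mixture phasor.  Equals the lifetime
    itself for a mono-exponential decay and increases strictly with the
    long-component fraction of a two-component mixture.
    """
    ph = mixture_phasor(decay, frequency_hz)
    if ph.g <= 0:
        raise ValueError("mixture phasor has non-positive g; no phase lifetime")
    omega = 2.0 * np.pi * frequency_hz
    return float(ph.s / ph.g / omega * NS_PER_S)


def solve_long_fraction(
    target_tau_ns: float | np.ndarray,
    tau_long_ns: float,
    tau_short_ns: float,
    frequency_hz: float,
) -> float | np.ndarray:
    """Intensity fraction of the long component reproducing a target phase lifetime.

    Inverts :func:`apparent_phase_lifetime` for a two-component mixture in
    closed form: with ``t = omega * tau_target`` and component phasors
    ``(g1, s1)``, ``(g2, s2)``,

    ``alpha = (t*g2 - s2) / ((s1 - s2) - t*(g1 - g2))``.

    The target must satisfy ``tau_short < target <= tau_long``.
    """
    if not tau_long_ns > tau_short_ns > 0:
        raise ValueError("need tau_long > tau_short > 0")
    target = np.asarray(target_tau_ns, dtype=float)
    if np.any(target <= tau_short_ns) or np.any(target > tau_long_ns):
        raise ValueError(
            f"target lifetime must lie in ({tau_short_ns}, {tau_long_ns}] ns"
        )
    omega = 2.0 * np.pi * frequency_hz
    p1 = lifetime_to_phasor(tau_long_ns, frequency_hz)
    p2 = lifetime_to_phasor(tau_short_ns, frequency_hz)
    t = omega * target / NS_PER_S
    alpha = (t * p2.g - p2.s) / ((p1.s - p2.s) - t * (p1.g - p2.g))
    return alpha if alpha.ndim else float(alpha)


# ---------------------------------------------------------------------------
# Map reconstruction


def map_from_demodulation(
    demod: DemodulationResult,
    calibration: CalibrationReference,
    channel: Channel,
) -> LifetimeMap:
    """Convert a demodulation result into a calibrated lifetime map.

    The instrument phase is subtracted from the measured phase; calibrated
    phases outside ``[0, pi/2)`` (noise-driven negatives, or saturated
    tangent) are marked invalid rather than wrapped, which avoids spuriously
    huge lifetimes.  The DC image is carried through for downstream intensity
    thresholding.
    """
    phase_cal = _wrap_to_pi(demod.phase_rad - calibration.instrument_phase_rad)
    tau = phase_lifetime(phase_cal, calibration.config.frequency_hz)
    valid = demod.valid & np.isfinite(tau)
    tau = np.where(valid, tau, np.nan)
    return LifetimeMap(tau_ns=tau, valid=valid, channel=channel, dc=demod.dc)


def reconstruct_map(
    stack: RawFrameStack, calibration: CalibrationReference
) -> LifetimeMap:
    """Demodulate a raw stack and convert calibrated phase to a lifetime map."""
    if stack.config != calibration.config:
        raise ValueError("stack and calibration use different modulation configs")
    return map_from_demodulation(demodulate(stack), calibration, stack.channel)
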