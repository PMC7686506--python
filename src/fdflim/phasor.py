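"""Phasor-plot analysis of cumulative decay clouds.

Every pixel's demodulation result maps to a phasor ``(g, s) = (m cos phi,
m sin phi)`` after instrument correction.  Mono-exponential decays lie on
the universal semicircle ``(g - 1/2)^2 + s^2 = 1/4``; any two-component
mixture lies on the chord connecting its component phasors, so an
elongated interior cloud betrays a multi-exponential decay and the chord's
two semicircle intersections identify the component lifetimes
(``tau = s / (g * omega)`` at each intersection).

The chord is fitted by total least squares (principal axis of the (g, s)
covariance) because both phasor coordinates carry noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CalibrationReference,
    DemodulationResult,
    RawFrameStack,
    _wrap_to_pi,
    demodulate,
)

__all__ = [
    "PhasorCloud",
    "ChordFit",
    "calibrated_phasors",
    "phasor_cloud",
    "fit_chord",
    "classify_decay",
]

NS_PER_S = 1e9
MIN_AXIS_RATIO = 1.5  # below this the cloud is too isotropic for a chord


@dataclass
class PhasorCloud:
    """Pooled calibrated phasor points with per-point provenance."""

    g: np.ndarray
    s: np.ndarray
    frequency_hz: float
    sample_id: np.ndarray | None = None
    channel: str = ""

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float).ravel()
        self.s = np.asarray(self.s, dtype=float).ravel()
        if self.g.shape != self.s.shape:
            raise ValueError("g and s must have equal length")
        if not (np.all(np.isfinite(self.g)) and np.all(np.isfinite(self.s))):
            raise ValueError("phasor coordinates must be finite")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"g": self.g, "s": self.s})
        df.insert(0, "channel", self.channel)
        if self.sample_id is not None:
            df.insert(0, "sample_id", self.sample_id)
        return df


@dataclass
class ChordFit:
    """Total-least-squares chord and its semicircle intersections."""

    normal: tuple[float, float]  # unit normal of the fitted line
    offset: float  # line: normal . p = offset
    intersections: list[tuple[float, float]]
    tau_short_ns: float | None
    tau_long_ns: float | None
    residual_rms: float
    axis_ratio: float
    ill_conditioned: bool
    intersects_circle: bool
    notes: list[str] = field(default_factory=list)


def calibrated_phasors(
    demod: DemodulationResult,
    calibration: CalibrationReference,
    select: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Instrument-corrected per-pixel phasor coordinates.

    The instrument phase is subtracted and the modulation divided by the
    instrument gain; ``select`` (boolean mask or (n, 2) coordinate array)
    restricts the pixels.
    """
    phase = demod.phase_rad
    mod = demod.modulation
    if select is not None:
        select = np.asarray(select)
        if select.dtype == bool:
            phase, mod = phase[select], mod[select]
        else:
            phase = phase[select[:, 0], select[:, 1]]
            mod = mod[select[:, 0], select[:, 1]]
    phase_cal = _wrap_to_pi(phase - calibration.instrument_phase_rad)
    m_cal = mod / calibration.instrument_modulation
    return m_cal * np.cos(phase_cal), m_cal * np.sin(phase_cal)


def phasor_cloud(
    stacks: list[RawFrameStack],
    calibration: CalibrationReference,
    selections: list[np.ndarray] | None = None,
    sample_ids: list[str] | None = None,
    channel: str = "",
) -> PhasorCloud:
    """Pool calibrated phasors over samples, restricted to selected pixels.

    ``selections`` typically holds the same per-sample random coordinates
    used for the lifetime statistics, so the cloud and the statistics see
    identical pixels.
    """
    gs: list[np.ndarray] = []
    ss: list[np.ndarray] = []
    ids: list[np.ndarray] = []
    for i, stack in enumerate(stacks):
        demod = demodulate(stack)
        sel = selections[i] if selections is not None else demod.valid
        g, s = calibrated_phasors(demod, calibration, sel)
        ok = np.isfinite(g) & np.isfinite(s)
        gs.append(g[ok])
        ss.append(s[ok])
        if sample_ids is not None:
            ids.append(np.repeat(sample_ids[i], int(ok.sum())))
    return PhasorCloud(
        g=np.concatenate(gs),
        s=np.concatenate(ss),
        frequency_hz=calibration.config.frequency_hz,
        sample_id=np.concatenate(ids) if ids else None,
        channel=channel,
    )


def _intersection_tau_ns(g: float, s: float, omega: float) -> float | None:
    """Lifetime of a semicircle point; None encodes the unbounded limit g -> 0."""
    if g <= 0:
        return None if s >= 0 else np.nan
    return float(s / (g * omega) * NS_PER_S)


def fit_chord(cloud: PhasorCloud) -> ChordFit:
    """Fit the principal-axis (TLS) line and intersect it with the semicircle.

    The two intersection lifetimes are the chord estimates of the short and
    long decay components.  Degenerate geometry is reported, not raised: a
    near-isotropic cloud sets ``ill_conditioned`` (axis ratio < 1.5) and a
    line missing the circle sets ``intersects_circle = False``.
    """
    pts = np.column_stack([cloud.g, cloud.s])
    if len(np.unique(pts, axis=0)) < 2:
        return ChordFit(
            normal=(np.nan, np.nan), offset=np.nan, intersections=[],
            tau_short_ns=None, tau_long_ns=None, residual_rms=0.0,
            axis_ratio=np.inf if len(pts) else np.nan, ill_conditioned=True,
            intersects_circle=False, notes=["fewer than two distinct points"],
        )
    mean = pts.mean(axis=0)
    cov = np.cov((pts - mean).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    direction = evecs[:, -1]
    normal = evecs[:, 0]
    with np.errstate(divide="ignore"):
        axis_ratio = float(
            np.sqrt(evals[-1] / evals[0]) if evals[0] > 0 else np.inf
        )
    offset = float(normal @ mean)
    residuals = (pts - mean) @ normal
    residual_rms = float(np.sqrt(np.mean(residuals**2)))
    notes: list[str] = []
    ill = axis_ratio < MIN_AXIS_RATIO
    if ill:
        notes.append(f"axis ratio {axis_ratio:.2f} < {MIN_AXIS_RATIO}: cloud nearly isotropic")

    # line: p(t) = p0 + t * direction, with p0 the foot of the mean on the line
    p0 = mean
    center = np.array([0.5, 0.0])
    dp = p0 - center
    b = 2.0 * float(dp @ direction)
    c = float(dp @ dp) - 0.25
    disc = b * b - 4.0 * c
    if disc < 0:
        return ChordFit(
            normal=tuple(normal), offset=offset, intersections=[],
            tau_short_ns=None, tau_long_ns=None, residual_rms=residual_rms,
            axis_ratio=axis_ratio, ill_conditioned=ill, intersects_circle=False,
            notes=notes + ["fitted line does not intersect the universal circle"],
        )
    sq = np.sqrt(disc)
    omega = 2.0 * np.pi * cloud.frequency_hz
    inters = []
    taus = []
    for t in ((-b - sq) / 2.0, (-b + sq) / 2.0):
        p = p0 + t * direction
        inters.append((float(p[0]), float(p[1])))
        taus.append(_intersection_tau_ns(float(p[0]), float(p[1]), omega))
    if any(t is None for t in taus):
        notes.append("one intersection at g <= 0: component lifetime unbounded")
    finite = sorted(t for t in taus if t is not None and np.isfinite(t))
    tau_short = finite[0] if finite else None
    if len(finite) == 2:
        tau_long = finite[1]
    elif any(t is None for t in taus):
        tau_long = None  # unbounded
    else:
        tau_long = tau_short
    if ill:
        tau_short = tau_long = None
        notes.append("component estimates suppressed: ill-conditioned geometry")
    return ChordFit(
        normal=(float(normal[0]), float(normal[1])), offset=offset,
        intersections=inters, tau_short_ns=tau_short, tau_long_ns=tau_long,
        residual_rms=residual_rms, axis_ratio=axis_ratio, ill_conditioned=ill,
        intersects_circle=True, notes=notes,
    )


def _semicircle_distance(g: np.ndarray, s: np.ndarray) -> np.ndarray:
    return np.abs(np.hypot(g - 0.5, s) - 0.5)


def classify_decay(cloud: PhasorCloud, tolerance: float = 0.01) -> str:
    """Label a cloud ``mono_exponential``, ``multi_exponential`` or ``indeterminate``.

    A tight cloud on the universal semicircle indicates a single-exponential
    decay; an elongated cloud strictly inside it indicates a mixture.
    """
    dist = _semicircle_distance(cloud.g, cloud.s)
    rms_dist = float(np.sqrt(np.mean(dist**2)))
    pts = np.column_stack([cloud.g, cloud.s])
    spread = float(np.sqrt(np.cov(pts.T).trace())) if len(pts) > 1 else 0.0
    if rms_dist <= tolerance and spread <= 5 * tolerance:
        return "mono_exponential"
    centroid_r = float(np.hypot(cloud.g.mean() - 0.5, cloud.s.mean()))
    fit = fit_chord(cloud)
    if (
        not fit.ill_conditioned
        and fit.axis_ratio >= MIN_AXIS_RATIO
        and centroid_r < 0.5 - tolerance
    ):
        return "multi_exponential"
    return "indeterminate"
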