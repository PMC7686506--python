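"""Post-processing of lifetime maps for statistical analysis.

Mirrors the standard post-acquisition chain for macroscopic FLIM of tissue
samples: restrict to the manually segmented sample region, discard pixels
with unphysical lifetimes (NADH >= 5 ns can only be vessels or artifacts;
PPIX >= 17 ns exceeds the pure-compound lifetime) or with intensity below
the background noise floor, and then draw a fixed number of random pixels
per sample so that large and small tissue pieces contribute equally to the
downstream statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Channel, LifetimeMap

__all__ = [
    "MaskConfig",
    "SamplingConfig",
    "EmptyMaskError",
    "apply_mask",
    "sample_pixels",
    "sample_coordinates",
    "build_cohort_table",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_NS = {Channel.NADH: 5.0, Channel.PPIX: 17.0}


class EmptyMaskError(ValueError):
    """No pixel survived masking; the sample is unusable."""


@dataclass(frozen=True)
class MaskConfig:
    """Outlier-mask settings: lifetime ceilings and intensity noise floor.

    ``noise_floor_mode='dark_stats'`` computes the floor as
    ``dark mean + noise_floor_k * dark SD`` from a dark measurement;
    ``'fixed'`` uses ``fixed_floor`` counts directly (the natural choice for
    synthetic data without dark frames).
    """

    nadh_max_ns: float = 5.0
    ppix_max_ns: float = 17.0
    noise_floor_mode: str = "fixed"  # "fixed" | "dark_stats"
    noise_floor_k: float = 2.0
    fixed_floor: float = 50.0

    def __post_init__(self) -> None:
        if self.nadh_max_ns <= 0 or self.ppix_max_ns <= 0:
            raise ValueError("lifetime thresholds must be positive")
        if self.noise_floor_mode not in ("fixed", "dark_stats"):
            raise ValueError("noise_floor_mode must be 'fixed' or 'dark_stats'")

    def max_ns(self, channel: Channel) -> float:
        return self.nadh_max_ns if channel is Channel.NADH else self.ppix_max_ns

    def floor(self, dark_stats: tuple[float, float] | None = None) -> float:
        if self.noise_floor_mode == "fixed":
            return self.fixed_floor
        if dark_stats is None:
            raise ValueError("dark_stats mode requires (dark_mean, dark_sd)")
        mean, sd = dark_stats
        return mean + self.noise_floor_k * sd


@dataclass(frozen=True)
class SamplingConfig:
    """Per-sample random pixel sampling: 100 representative pixels by default."""

    n_points: int = 100
    seed: int = 0
    replacement_policy: str = "with_replacement_warn"  # or "error"

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.replacement_policy not in ("with_replacement_warn", "error"):
            raise ValueError("unknown replacement_policy")


def apply_mask(
    lifetime_map: LifetimeMap,
    segmentation: np.ndarray,
    config: MaskConfig | None = None,
    dark_stats: tuple[float, float] | None = None,
) -> LifetimeMap:
    """Intersect validity with segmentation, lifetime ceiling and noise floor.

    A pixel survives iff it lies inside the segmented region, demodulated
    validly, has a lifetime strictly below the channel ceiling, and a DC
    intensity at or above the noise floor.  Everything else is excluded from
    every downstream computation.  Raises :class:`EmptyMaskError` if nothing
    survives.
    """
    config = MaskConfig() if config is None else config
    segmentation = np.asarray(segmentation, dtype=bool)
    if segmentation.shape != lifetime_map.tau_ns.shape:
        raise ValueError("segmentation and lifetime map shapes disagree")
    floor = config.floor(dark_stats)
    with np.errstate(invalid="ignore"):
        below_ceiling = lifetime_map.tau_ns < config.max_ns(lifetime_map.channel)
    valid = (
        segmentation
        & lifetime_map.valid
        & np.where(np.isnan(lifetime_map.tau_ns), False, below_ceiling)
        & (lifetime_map.dc >= floor)
    )
    if not valid.any():
        raise EmptyMaskError(
            f"no {lifetime_map.channel.value} pixel survived masking"
        )
    tau = np.where(valid, lifetime_map.tau_ns, np.nan)
    return LifetimeMap(
        tau_ns=tau, valid=valid, channel=lifetime_map.channel, dc=lifetime_map.dc
    )


def sample_coordinates(
    valid: np.ndarray, config: SamplingConfig, stream_key: str = ""
) -> np.ndarray:
    """Uniform draw without replacement of ``n_points`` valid pixel coordinates.

    Returns an ``(n_points, 2)`` array of 0-based (row, col) pairs.  The rng
    stream is keyed by ``(seed, stream_key)`` so each (sample, channel) pair
    gets a reproducible, order-independent draw.  If fewer valid pixels exist
    than requested, the policy either raises or draws with replacement and
    warns.
    """
    import zlib

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(stream_key.encode())])
    )
    rows, cols = np.nonzero(valid)
    n_valid = rows.size
    if n_valid == 0:
        raise EmptyMaskError("cannot sample from an empty mask")
    if n_valid < config.n_points:
        if config.replacement_policy == "error":
            raise ValueError(
                f"only {n_valid} valid pixels for {config.n_points} requested"
            )
        warnings.warn(
            f"{stream_key or 'sample'}: only {n_valid} valid pixels; "
            f"drawing {config.n_points} with replacement",
            stacklevel=2,
        )
        idx = rng.choice(n_valid, size=config.n_points, replace=True)
    else:
        idx = rng.choice(n_valid, size=config.n_points, replace=False)
    return np.column_stack([rows[idx], cols[idx]])


def sample_pixels(
    lifetime_map: LifetimeMap, config: SamplingConfig, stream_key: str = ""
) -> tuple[np.ndarray, np.ndarray]:
    """Sample lifetimes at random valid coordinates; returns (values, coords)."""
    coords = sample_coordinates(lifetime_map.valid, config, stream_key)
    values = lifetime_map.tau_ns[coords[:, 0], coords[:, 1]]
    return values, coords


def build_cohort_table(
    sampled: list[dict],
) -> pd.DataFrame:
    """Assemble the long-format cohort table, one row per sampled pixel.

    ``sampled`` holds one dict per sample with keys ``patient_id, sample_id,
    diagnosis, grade, tissue, ala, coords, tau_nadh_ns, tau_ppix_ns`` where
    the NADH and PPIX values are colocalized (drawn at the same coordinates
    from the intersection of both channels' valid masks).  Row count equals
    ``n_samples * n_points``.
    """
    frames = []
    for entry in sampled:
        for key in ("tau_nadh_ns", "tau_ppix_ns"):
            if key not in entry:
                raise ValueError(f"sample {entry.get('sample_id')} missing {key}")
        nadh = np.asarray(entry["tau_nadh_ns"], dtype=float)
        ppix = np.asarray(entry["tau_ppix_ns"], dtype=float)
        if nadh.shape != ppix.shape:
            raise ValueError("colocalized channels must have equal counts")
        coords = np.asarray(entry["coords"])
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": entry["patient_id"],
                    "sample_id": entry["sample_id"],
                    "diagnosis": entry.get("diagnosis", ""),
                    "grade": entry["grade"],
                    "tissue": entry["tissue"],
                    "ala": entry["ala"],
                    "row": coords[:, 0],
                    "col": coords[:, 1],
                    "tau_nadh_ns": nadh,
                    "tau_ppix_ns": ppix,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
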