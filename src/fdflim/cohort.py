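"""Synthetic FLIM study cohort generator.

Emulates a 42-sample / 21-patient brain-tumor cohort as acquired by a
macroscopic frequency-domain FLIM system: for each tissue sample a pair of
phase-stepped homodyne frame stacks (NADH and PPIX channels), a segmentation
mask, and metadata (diagnosis, tumor grade, tissue histology, intraoperative
5-ALA fluorescence status).

Per-sample apparent lifetimes are drawn from lognormal distributions matched
to published group medians and interquartile ranges, then realized physically
as two-component decay mixtures: PPIX as native PPIX (~16 ns) diluted by
short-lived tissue autofluorescence (~1.9 ns), NADH as a bound (~4 ns) /
free (~0.4 ns) mixture.  Shot noise, sub-field-of-view elliptical sample
shapes, vessel streaks (long NADH lifetime) and necrotic cores (short NADH,
reduced PPIX) complete the forward model, so that every downstream stage of
the analysis pipeline can be exercised without access to patient data.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Channel,
    DecayModel,
    ModulationConfig,
    RawFrameStack,
    lifetime_to_phasor,
    solve_long_fraction,
    synthesize_stack,
)

__all__ = [
    "Tissue",
    "Grade",
    "AlaStatus",
    "TissueClassParams",
    "AlaGroupParams",
    "SampleSpec",
    "CohortConfig",
    "SampleRecord",
    "TISSUE_PARAMS",
    "ALA_PARAMS",
    "default_inventory",
    "draw_sample_lifetime",
    "generate_sample",
    "generate_cohort",
    "simulate_reference",
    "write_cohort",
    "load_cohort",
]

Z_75 = 0.6744897501960817  # 75% standard-normal quantile


class Tissue(str, enum.Enum):
    NPL = "NPL"  # non-pathological parenchyma
    REA = "REA"  # reactive parenchyma
    INF = "INF"  # infiltration zone
    NEC = "NEC"  # necrotic area
    TUM = "TUM"  # compact tumor


class Grade(str, enum.Enum):
    LGG = "LGG"
    HGG = "HGG"
    MET = "MET"


class AlaStatus(str, enum.Enum):
    ALA_POS = "ALA+"
    ALA_NEG = "ALA-"


@dataclass(frozen=True)
class TissueClassParams:
    """Median and quartiles (ns) of the apparent lifetime per tissue class."""

    label: Tissue
    nadh_median_ns: float
    nadh_q25_ns: float
    nadh_q75_ns: float
    ppix_median_ns: float
    ppix_q25_ns: float
    ppix_q75_ns: float

    def __post_init__(self) -> None:
        for lo, mid, hi in (
            (self.nadh_q25_ns, self.nadh_median_ns, self.nadh_q75_ns),
            (self.ppix_q25_ns, self.ppix_median_ns, self.ppix_q75_ns),
        ):
            if not (0 < lo <= mid <= hi):
                raise ValueError("need 0 < q25 <= median <= q75")


@dataclass(frozen=True)
class AlaGroupParams:
    """PPIX lifetime summary (ns) conditioned on intraoperative fluorescence."""

    status: AlaStatus
    ppix_median_ns: float
    ppix_q25_ns: float
    ppix_q75_ns: float

    def __post_init__(self) -> None:
        if not (0 < self.ppix_q25_ns <= self.ppix_median_ns <= self.ppix_q75_ns):
            raise ValueError("need 0 < q25 <= median <= q75")


# Group targets: NADH/PPIX medians [q25; q75] per tissue class and, for the
# ALA conditioning, PPIX medians per intraoperative fluorescence status.
TISSUE_PARAMS: dict[Tissue, TissueClassParams] = {
    Tissue.NPL: TissueClassParams(Tissue.NPL, 1.2, 1.2, 1.3, 1.9, 1.6, 2.1),
    Tissue.REA: TissueClassParams(Tissue.REA, 2.5, 1.8, 3.0, 8.2, 7.4, 9.1),
    Tissue.INF: TissueClassParams(Tissue.INF, 1.7, 1.4, 2.1, 3.2, 2.3, 5.7),
    Tissue.NEC: TissueClassParams(Tissue.NEC, 2.4, 1.4, 2.6, 6.3, 3.6, 6.8),
    Tissue.TUM: TissueClassParams(Tissue.TUM, 1.8, 1.7, 2.1, 11.3, 6.6, 12.9),
}

ALA_PARAMS: dict[AlaStatus, AlaGroupParams] = {
    AlaStatus.ALA_POS: AlaGroupParams(AlaStatus.ALA_POS, 11.0, 8.2, 12.9),
    AlaStatus.ALA_NEG: AlaGroupParams(AlaStatus.ALA_NEG, 3.0, 2.3, 5.0),
}


@dataclass(frozen=True)
class SampleSpec:
    """One inventory row: who the sample came from and how it was labeled."""

    patient_id: int
    sample_id: str
    diagnosis: str
    grade: Grade
    tissue: Tissue
    ala: AlaStatus


# (patient, diagnosis, grade, [(tissue, ala), ...]) for the 21 patients;
# 42 samples total, 21 ALA+ / 21 ALA-, tissue counts NPL 2 / REA 5 / INF 12 /
# NEC 7 / TUM 16, grade partition LGG 7 / HGG 24 / MET 11 samples.
_INVENTORY_ROWS: list[tuple[int, str, Grade, list[tuple[Tissue, AlaStatus]]]] = [
    (1, "Diffuse astrocytoma", Grade.LGG,
     [(Tissue.TUM, AlaStatus.ALA_NEG)] * 3),
    (2, "Diffuse astrocytoma", Grade.LGG,
     [(Tissue.INF, AlaStatus.ALA_NEG)] * 2),
    (3, "Oligodendroglioma", Grade.LGG,
     [(Tissue.INF, AlaStatus.ALA_NEG)] * 2),
    (4, "Anaplastic astrocytoma", Grade.HGG,
     [(Tissue.TUM, AlaStatus.ALA_NEG), (Tissue.TUM, AlaStatus.ALA_POS)]),
    (5, "Anaplastic oligodendroglioma", Grade.HGG,
     [(Tissue.NPL, AlaStatus.ALA_NEG)]),
    (6, "Glioblastoma", Grade.HGG,
     [(Tissue.INF, AlaStatus.ALA_NEG), (Tissue.TUM, AlaStatus.ALA_POS)]),
    (7, "Glioblastoma", Grade.HGG,
     [(Tissue.INF, AlaStatus.ALA_NEG), (Tissue.NEC, AlaStatus.ALA_POS)]),
    (8, "Glioblastoma", Grade.HGG,
     [(Tissue.INF, AlaStatus.ALA_NEG), (Tissue.TUM, AlaStatus.ALA_POS)]),
    (9, "Glioblastoma", Grade.HGG,
     [(Tissue.INF, AlaStatus.ALA_POS), (Tissue.NEC, AlaStatus.ALA_POS)]),
    (10, "Glioblastoma", Grade.HGG,
     [(Tissue.NEC, AlaStatus.ALA_NEG), (Tissue.TUM, AlaStatus.ALA_POS)]),
    (11, "Glioblastoma", Grade.HGG,
     [(Tissue.NEC, AlaStatus.ALA_NEG), (Tissue.TUM, AlaStatus.ALA_POS)]),
    (12, "Glioblastoma", Grade.HGG,
     [(Tissue.INF, AlaStatus.ALA_NEG), (Tissue.TUM, AlaStatus.ALA_POS)]),
    (13, "Glioblastoma", Grade.HGG, [(Tissue.INF, AlaStatus.ALA_POS)]),
    (14, "Glioblastoma", Grade.HGG, [(Tissue.TUM, AlaStatus.ALA_POS)]),
    (15, "Glioblastoma", Grade.HGG, [(Tissue.TUM, AlaStatus.ALA_POS)]),
    (16, "Glioblastoma", Grade.HGG,
     [(Tissue.INF, AlaStatus.ALA_POS), (Tissue.TUM, AlaStatus.ALA_POS)]),
    (17, "Glioblastoma", Grade.HGG,
     [(Tissue.NPL, AlaStatus.ALA_NEG), (Tissue.TUM, AlaStatus.ALA_POS)]),
    (18, "Metastasis (primary: lung)", Grade.MET,
     [(Tissue.REA, AlaStatus.ALA_POS), (Tissue.INF, AlaStatus.ALA_NEG),
      (Tissue.TUM, AlaStatus.ALA_POS)]),
    (19, "Metastasis (primary: lung)", Grade.MET,
     [(Tissue.REA, AlaStatus.ALA_POS), (Tissue.NEC, AlaStatus.ALA_NEG)]),
    (20, "Metastasis (primary: lung)", Grade.MET,
     [(Tissue.REA, AlaStatus.ALA_NEG), (Tissue.REA, AlaStatus.ALA_POS),
      (Tissue.NEC, AlaStatus.ALA_NEG)]),
    (21, "Metastasis (primary: heart)", Grade.MET,
     [(Tissue.REA, AlaStatus.ALA_POS), (Tissue.NEC, AlaStatus.ALA_NEG),
      (Tissue.TUM, AlaStatus.ALA_POS)]),
]


def default_inventory() -> list[SampleSpec]:
    """The default cohort inventory: 42 samples from 21 patients."""
    specs: list[SampleSpec] = []
    for patient, diagnosis, grade, samples in _INVENTORY_ROWS:
        for idx, (tissue, ala) in enumerate(samples, start=1):
            specs.append(
                SampleSpec(
                    patient_id=patient,
                    sample_id=f"P{patient:02d}-S{idx}",
                    diagnosis=diagnosis,
                    grade=grade,
                    tissue=tissue,
                    ala=ala,
                )
            )
    return specs


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort forward model.

    ``mode`` selects which conditioning drives the PPIX sample lifetimes:
    ``"tissue"`` draws them from the per-tissue-class parameters, ``"ala"``
    from the intraoperative-fluorescence groups.  NADH lifetimes are always
    tissue-conditioned, and non-pathological samples always use their own
    class parameters for both channels.
    """

    mode: str = "tissue"  # "tissue" | "ala"
    inventory: list[SampleSpec] = field(default_factory=default_inventory)
    modulation: ModulationConfig = field(default_factory=ModulationConfig)
    image_size: int = 256
    photon_budget: float = 1000.0  # mean DC counts/frame inside the sample
    background_counts: float = 10.0
    pixel_jitter_cv: float = 0.05
    ppix_components_ns: tuple[float, float] = (16.0, 1.9)  # (long, short)
    nadh_components_ns: tuple[float, float] = (4.0, 0.4)  # (bound, free)
    clip_margin_ns: float = 0.05
    vessel_lifetime_ns: float = 5.5
    vessel_fraction: float = 0.3
    necrotic_core_nadh_ns: float = 0.7
    necrotic_core_ppix_factor: float = 0.6
    necrotic_core_area_fraction: float = 0.1
    instrument_phase_rad: float = 0.2
    instrument_modulation: float = 0.85
    noise: str = "poisson"
    exposure_ms: dict[str, float] = field(
        default_factory=lambda: {"NADH": 200.0, "PPIX": 100.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("tissue", "ala"):
            raise ValueError("mode must be 'tissue' or 'ala'")
        if not self.inventory:
            raise ValueError("inventory must be non-empty")
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")
        for long_ns, short_ns in (self.ppix_components_ns, self.nadh_components_ns):
            if not long_ns > short_ns > 0:
                raise ValueError("component lifetimes must be ordered long > short > 0")

    def components(self, channel: Channel) -> tuple[float, float]:
        return (
            self.nadh_components_ns
            if channel is Channel.NADH
            else self.ppix_components_ns
        )

    def feasible_range(self, channel: Channel) -> tuple[float, float]:
        """Apparent-lifetime interval realizable as a two-component mixture."""
        long_ns, short_ns = self.components(channel)
        eps = self.clip_margin_ns
        return short_ns + eps, long_ns - eps


@dataclass
class SampleRecord:
    """Ground truth plus raw acquisition for one synthetic tissue sample."""

    spec: SampleSpec
    true_tau_ns: dict[str, float]  # channel -> drawn apparent lifetime
    stacks: dict[str, RawFrameStack]  # channel -> raw homodyne stack
    mask: np.ndarray  # boolean segmentation mask (sample region)
    true_tau_maps: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.stacks.values()}
        if len(shapes) != 1 or next(iter(shapes)) != self.mask.shape:
            raise ValueError("stacks and mask must share a shape")
        if not self.mask.any():
            raise ValueError("segmentation mask is empty")


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Independent, order-invariant stream per (cohort seed, sample id)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(sample_id.encode())])
    )


def draw_sample_lifetime(
    median_ns: float,
    q25_ns: float,
    q75_ns: float,
    rng: np.random.Generator,
    clip_range_ns: tuple[float, float] | None = None,
) -> float:
    """Draw one apparent lifetime from a lognormal matched to median and IQR.

    ``sigma = ln(q75/q25) / (2 * z_0.75)`` so the fitted lognormal reproduces
    both quartiles; the draw is censored to ``clip_range_ns`` (the feasible
    mixture interval of the channel).  Censoring happens in the tails, so the
    distribution median is preserved whenever the median itself is feasible.
    """
    sigma = np.log(q75_ns / q25_ns) / (2.0 * Z_75)
    tau = float(median_ns * np.exp(sigma * rng.standard_normal()))
    if clip_range_ns is not None:
        tau = float(np.clip(tau, *clip_range_ns))
    return tau


def _elliptical_mask(
    shape: tuple[int, int],
    rng: np.random.Generator,
    *,
    center: tuple[float, float] | None = None,
    axis_range: tuple[float, float] = (0.22, 0.42),
) -> np.ndarray:
    """Random rotated ellipse, strictly smaller than the field of view."""
    h, w = shape
    if center is None:
        cy = h / 2 + rng.uniform(-0.08, 0.08) * h
        cx = w / 2 + rng.uniform(-0.08, 0.08) * w
    else:
        cy, cx = center
    a = rng.uniform(*axis_range) * h
    b = rng.uniform(*axis_range) * w
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _vessel_mask(
    mask: np.ndarray, rng: np.random.Generator, width_px: float = 2.0
) -> np.ndarray:
    """A straight streak of given half-width crossing the sample region."""
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    theta = rng.uniform(0, np.pi)
    offset = rng.uniform(-0.2, 0.2) * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.abs(
        (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta) - offset
    )
    return mask & (dist <= width_px)


def _jitter(
    tau_ns: float, shape: tuple[int, int], cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal per-pixel scatter around a sample lifetime, median-preserving."""
    if cv <= 0:
        return np.full(shape, tau_ns)
    sigma = np.sqrt(np.log1p(cv**2))
    return tau_ns * np.exp(sigma * rng.standard_normal(shape))


def _tau_field_to_phasor(
    tau_map: np.ndarray, components: tuple[float, float], frequency_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mixture phasor realizing an apparent-lifetime field."""
    long_ns, short_ns = components
    alpha = solve_long_fraction(tau_map, long_ns, short_ns, frequency_hz)
    p1 = lifetime_to_phasor(long_ns, frequency_hz)
    p2 = lifetime_to_phasor(short_ns, frequency_hz)
    g = alpha * p1.g + (1.0 - alpha) * p2.g
    s = alpha * p1.s + (1.0 - alpha) * p2.s
    return g, s


def _ppix_params(spec: SampleSpec, config: CohortConfig) -> tuple[float, float, float]:
    if spec.tissue is Tissue.NPL or config.mode == "tissue":
        p = TISSUE_PARAMS[spec.tissue]
        return p.ppix_median_ns, p.ppix_q25_ns, p.ppix_q75_ns
    a = ALA_PARAMS[spec.ala]
    return a.ppix_median_ns, a.ppix_q25_ns, a.ppix_q75_ns


def generate_sample(
    spec: SampleSpec,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> SampleRecord:
    """Generate raw stacks, mask and ground truth for one inventory row."""
    rng = _sample_rng(config.seed, spec.sample_id) if rng is None else rng
    shape = (config.image_size, config.image_size)
    freq = config.modulation.frequency_hz

    tissue_p = TISSUE_PARAMS[spec.tissue]
    nadh_range = config.feasible_range(Channel.NADH)
    ppix_range = config.feasible_range(Channel.PPIX)
    tau_nadh = draw_sample_lifetime(
        tissue_p.nadh_median_ns, tissue_p.nadh_q25_ns, tissue_p.nadh_q75_ns,
        rng, nadh_range,
    )
    med, q25, q75 = _ppix_params(spec, config)
    tau_ppix = draw_sample_lifetime(med, q25, q75, rng, ppix_range)

    mask = _elliptical_mask(shape, rng)

    # per-pixel apparent lifetime fields
    nadh_map = np.clip(_jitter(tau_nadh, shape, config.pixel_jitter_cv, rng), *nadh_range)
    ppix_map = np.clip(_jitter(tau_ppix, shape, config.pixel_jitter_cv, rng), *ppix_range)

    if spec.tissue is Tissue.NEC:
        scale = np.sqrt(config.necrotic_core_area_fraction)
        ys, xs = np.nonzero(mask)
        cy = ys.mean() + rng.uniform(-0.05, 0.05) * shape[0]
        cx = xs.mean() + rng.uniform(-0.05, 0.05) * shape[1]
        core = mask & _elliptical_mask(
            shape, rng, center=(cy, cx),
            axis_range=(0.25 * scale, 0.45 * scale),
        )
        core_nadh = np.clip(
            _jitter(config.necrotic_core_nadh_ns, shape, config.pixel_jitter_cv, rng),
            *nadh_range,
        )
        nadh_map = np.where(core, core_nadh, nadh_map)
        ppix_map = np.where(
            core, np.clip(ppix_map * config.necrotic_core_ppix_factor, *ppix_range),
            ppix_map,
        )

    has_vessel = rng.random() < config.vessel_fraction
    vessel = _vessel_mask(mask, rng) if has_vessel else np.zeros(shape, bool)

    g_nadh, s_nadh = _tau_field_to_phasor(nadh_map, config.nadh_components_ns, freq)
    g_ppix, s_ppix = _tau_field_to_phasor(ppix_map, config.ppix_components_ns, freq)
    if has_vessel and vessel.any():
        # vessels exceed the bound-NADH limit; modelled as a distinct
        # mono-exponential emitter rather than a bound/free mixture
        pv = lifetime_to_phasor(config.vessel_lifetime_ns, freq)
        g_nadh = np.where(vessel, pv.g, g_nadh)
        s_nadh = np.where(vessel, pv.s, s_nadh)
        nadh_map = np.where(vessel, config.vessel_lifetime_ns, nadh_map)

    dc = np.where(mask, config.photon_budget, config.background_counts)
    stacks: dict[str, RawFrameStack] = {}
    for channel, g, s in (
        (Channel.NADH, g_nadh, s_nadh),
        (Channel.PPIX, g_ppix, s_ppix),
    ):
        stacks[channel.value] = synthesize_stack(
            g, s, dc, config.modulation,
            instrument_phase_rad=config.instrument_phase_rad,
            instrument_modulation=config.instrument_modulation,
            noise=config.noise,
            rng=rng,
            channel=channel,
            exposure_ms=config.exposure_ms[channel.value],
        )

    return SampleRecord(
        spec=spec,
        true_tau_ns={Channel.NADH.value: tau_nadh, Channel.PPIX.value: tau_ppix},
        stacks=stacks,
        mask=mask,
        true_tau_maps={Channel.NADH.value: nadh_map, Channel.PPIX.value: ppix_map},
    )


def simulate_reference(
    config: CohortConfig, known_lifetime_ns: float = 0.0
) -> RawFrameStack:
    """Reference-target acquisition (default: ideal scatterer, tau = 0 ns)."""
    rng = _sample_rng(config.seed, "__reference__")
    decay = DecayModel.mono(known_lifetime_ns) if known_lifetime_ns > 0 else None
    shape = (config.image_size, config.image_size)
    if decay is None:
        g = np.ones(shape)
        s = np.zeros(shape)
    else:
        ph = lifetime_to_phasor(known_lifetime_ns, config.modulation.frequency_hz)
        g = np.full(shape, ph.g)
        s = np.full(shape, ph.s)
    return synthesize_stack(
        g, s, np.full(shape, config.photon_budget), config.modulation,
        instrument_phase_rad=config.instrument_phase_rad,
        instrument_modulation=config.instrument_modulation,
        noise=config.noise,
        rng=rng,
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Generate one record per inventory row plus a manifest table.

    Each sample gets its own rng stream derived from ``(seed, sample_id)``,
    so the cohort is reproducible independent of generation order.
    """
    ids = [s.sample_id for s in config.inventory]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in inventory")
    records = [generate_sample(spec, config) for spec in config.inventory]
    manifest = pd.DataFrame(
        {
            "patient_id": [r.spec.patient_id for r in records],
            "sample_id": [r.spec.sample_id for r in records],
            "diagnosis": [r.spec.diagnosis for r in records],
            "grade": [r.spec.grade.value for r in records],
            "tissue": [r.spec.tissue.value for r in records],
            "ala": [r.spec.ala.value for r in records],
            "true_tau_nadh_ns": [r.true_tau_ns["NADH"] for r in records],
            "true_tau_ppix_ns": [r.true_tau_ns["PPIX"] for r in records],
        }
    )
    return records, manifest


def write_cohort(
    records: list[SampleRecord],
    manifest: pd.DataFrame,
    config: CohortConfig,
    out_dir: str | Path,
) -> Path:
    """Write per-sample TIFF stacks, masks and truth plus cohort manifest/config."""
    from . import io as _io  # deferred: io imports tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        sample_dir = out / rec.spec.sample_id
        sample_dir.mkdir(exist_ok=True)
        for channel, stack in rec.stacks.items():
            _io.write_stack(sample_dir / f"{channel.lower()}.tif", stack)
        _io.write_mask(sample_dir / "mask.tif", rec.mask)
        (sample_dir / "truth.json").write_text(
            json.dumps(
                {
                    "sample_id": rec.spec.sample_id,
                    "true_tau_ns": rec.true_tau_ns,
                    "tissue": rec.spec.tissue.value,
                    "grade": rec.spec.grade.value,
                    "ala": rec.spec.ala.value,
                },
                indent=2,
            )
        )
    manifest.to_csv(out / "manifest.csv", index=False, float_format="%.6g")
    cfg = dataclasses.asdict(config)
    cfg["inventory"] = [dataclasses.asdict(s) for s in config.inventory]
    (out / "config.json").write_text(json.dumps(cfg, indent=2, default=str))
    return out


def load_cohort(cohort_dir: str | Path) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort` back into memory."""
    from . import io as _io

    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    records: list[SampleRecord] = []
    for row in manifest.itertuples():
        sample_dir = cohort_dir / row.sample_id
        truth = json.loads((sample_dir / "truth.json").read_text())
        spec = SampleSpec(
            patient_id=int(row.patient_id),
            sample_id=row.sample_id,
            diagnosis=row.diagnosis,
            grade=Grade(row.grade),
            tissue=Tissue(row.tissue),
            ala=AlaStatus(row.ala),
        )
        stacks = {
            ch: _io.read_stack(sample_dir / f"{ch.lower()}.tif")
            for ch in ("NADH", "PPIX")
        }
        records.append(
            SampleRecord(
                spec=spec,
                true_tau_ns=truth["true_tau_ns"],
                stacks=stacks,
                mask=_io.read_mask(sample_dir / "mask.tif"),
            )
        )
    return records, manifest
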