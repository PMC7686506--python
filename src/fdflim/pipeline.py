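"""End-to-end pipeline: synthetic cohort through statistics, phasors and CV.

One call runs the whole chain the study performs on a cohort: calibrate
against a reference target, reconstruct phase-lifetime maps for both
channels of every sample, mask out segmentation, lifetime-ceiling and
noise-floor violations, draw the per-sample random pixels (colocalized
across channels), assemble the long-format cohort table, compute per-sample
means, group summaries and Mann-Whitney comparisons, pool calibrated PPIX
phasors at the sampled pixels and fit the bi-exponential chord, and
(optionally) cross-validate the grade and tissue classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as _classify
from .cohort import CohortConfig, SampleRecord, generate_cohort, simulate_reference
from .core import (
    CalibrationReference,
    Channel,
    calibrate,
    demodulate,
    map_from_demodulation,
)
from .phasor import ChordFit, PhasorCloud, calibrated_phasors, fit_chord
from .preprocess import (
    EmptyMaskError,
    MaskConfig,
    SamplingConfig,
    apply_mask,
    build_cohort_table,
    sample_coordinates,
)
from .stats import pairwise_comparisons, summarize_groups, summarize_samples

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the pipeline computes for one cohort."""

    manifest: pd.DataFrame
    cohort_table: pd.DataFrame
    sample_summaries: pd.DataFrame
    group_summaries: dict[str, pd.DataFrame]
    pairwise_tests: pd.DataFrame
    ppix_cloud: PhasorCloud
    nadh_cloud: PhasorCloud
    ppix_chord: ChordFit
    calibration: CalibrationReference
    cv_results: dict[tuple[str, str], _classify.CVResult] = field(default_factory=dict)
    unusable_samples: list[str] = field(default_factory=list)

    def group_median(self, key: str, label: str, channel: str) -> float:
        df = self.group_summaries[key]
        row = df[df["label"] == label]
        if row.empty:
            raise KeyError(f"no group {label!r} under key {key!r}")
        return float(row[f"{channel.lower()}_median_ns"].iloc[0])

    def ala_test(self, channel: str = "PPIX"):
        df = self.pairwise_tests
        row = df[
            (df["channel"] == channel)
            & (df["group_a"].str.startswith("ALA"))
            & (df["group_b"].str.startswith("ALA"))
        ]
        return row.iloc[0]


def _process_sample(
    record: SampleRecord,
    calibration: CalibrationReference,
    mask_config: MaskConfig,
    sampling: SamplingConfig,
) -> tuple[dict | None, dict[str, np.ndarray]]:
    """Reconstruct, mask and sample one record; returns (table entry, phasors)."""
    maps = {}
    demods = {}
    for channel_name, stack in record.stacks.items():
        demod = demodulate(stack)
        demods[channel_name] = demod
        lt_map = map_from_demodulation(demod, calibration, Channel(channel_name))
        try:
            maps[channel_name] = apply_mask(lt_map, record.mask, mask_config)
        except EmptyMaskError:
            return None, {}

    combined_valid = maps["NADH"].valid & maps["PPIX"].valid
    if not combined_valid.any():
        return None, {}
    coords = sample_coordinates(combined_valid, sampling, record.spec.sample_id)
    entry = {
        "patient_id": record.spec.patient_id,
        "sample_id": record.spec.sample_id,
        "diagnosis": record.spec.diagnosis,
        "grade": record.spec.grade.value,
        "tissue": record.spec.tissue.value,
        "ala": record.spec.ala.value,
        "coords": coords,
        "tau_nadh_ns": maps["NADH"].tau_ns[coords[:, 0], coords[:, 1]],
        "tau_ppix_ns": maps["PPIX"].tau_ns[coords[:, 0], coords[:, 1]],
    }
    phasors = {}
    for channel_name, demod in demods.items():
        g, s = calibrated_phasors(demod, calibration, coords)
        ok = np.isfinite(g) & np.isfinite(s)
        phasors[channel_name] = (g[ok], s[ok])
    return entry, phasors


def run_pipeline(
    config: CohortConfig,
    mask_config: MaskConfig | None = None,
    sampling: SamplingConfig | None = None,
    classifier_config: _classify.ClassifierConfig | None = None,
    *,
    run_classification: bool = False,
    records: list[SampleRecord] | None = None,
    manifest: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full analysis chain on a (generated or supplied) cohort.

    The sampling seed defaults to the cohort seed so one integer reproduces
    the entire run.
    """
    mask_config = MaskConfig() if mask_config is None else mask_config
    if sampling is None:
        sampling = SamplingConfig(seed=config.seed)
    if records is None:
        records, manifest = generate_cohort(config)
    assert manifest is not None

    reference = simulate_reference(config)
    calibration = calibrate(reference, known_lifetime_ns=0.0)

    entries: list[dict] = []
    unusable: list[str] = []
    cloud_parts: dict[str, list[tuple[np.ndarray, np.ndarray, str]]] = {
        "NADH": [],
        "PPIX": [],
    }
    for record in records:
        entry, phasors = _process_sample(record, calibration, mask_config, sampling)
        if entry is None:
            unusable.append(record.spec.sample_id)
            logger.warning("sample %s unusable after masking", record.spec.sample_id)
            continue
        entries.append(entry)
        for channel_name, (g, s) in phasors.items():
            cloud_parts[channel_name].append((g, s, record.spec.sample_id))

    cohort_table = build_cohort_table(entries)
    summaries = summarize_samples(cohort_table)
    group_summaries = {
        key: summarize_groups(summaries, key) for key in ("tissue", "grade", "ala")
    }
    tests = pd.concat(
        [
            pairwise_comparisons(summaries, key, channel)
            for key in ("tissue", "grade", "ala")
            for channel in ("NADH", "PPIX")
        ],
        ignore_index=True,
    )

    clouds = {}
    for channel_name, parts in cloud_parts.items():
        clouds[channel_name] = PhasorCloud(
            g=np.concatenate([p[0] for p in parts]),
            s=np.concatenate([p[1] for p in parts]),
            frequency_hz=config.modulation.frequency_hz,
            sample_id=np.concatenate(
                [np.repeat(p[2], len(p[0])) for p in parts]
            ),
            channel=channel_name,
        )
    chord = fit_chord(clouds["PPIX"])

    result = PipelineResult(
        manifest=manifest,
        cohort_table=cohort_table,
        sample_summaries=summaries,
        group_summaries=group_summaries,
        pairwise_tests=tests,
        ppix_cloud=clouds["PPIX"],
        nadh_cloud=clouds["NADH"],
        ppix_chord=chord,
        calibration=calibration,
        unusable_samples=unusable,
    )

    if run_classification:
        base = classifier_config or _classify.ClassifierConfig(seed=config.seed)
        for feature_set in ("ppix_only", "nadh_ppix"):
            cfg = _classify.ClassifierConfig(
                n_learners=base.n_learners,
                learning_rate=base.learning_rate,
                max_tree_splits=base.max_tree_splits,
                undersample_ratio=base.undersample_ratio,
                n_folds=base.n_folds,
                seed=base.seed,
                feature_set=feature_set,
                patient_grouped_cv=base.patient_grouped_cv,
            )
            datasets = _classify.build_datasets(cohort_table, feature_set)
            for task, (X, y, patients) in datasets.items():
                result.cv_results[(task, feature_set)] = _classify.cross_validate(
                    X, y, cfg, task=task, groups=patients.to_numpy()
                )
    return result
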