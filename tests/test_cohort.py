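"""Synthetic cohort generator: inventory, lifetime draws, sample realism."""

from collections import Counter

import numpy as np
import pytest

from fdflim.cohort import (
    ALA_PARAMS,
    TISSUE_PARAMS,
    AlaStatus,
    CohortConfig,
    Grade,
    Tissue,
    default_inventory,
    draw_sample_lifetime,
    generate_cohort,
    generate_sample,
    simulate_reference,
)
from fdflim.core import calibrate, reconstruct_map


class TestInventory:
    def test_totals(self):
        inv = default_inventory()
        assert len(inv) == 42
        assert len({s.patient_id for s in inv}) == 21
        assert sum(s.ala is AlaStatus.ALA_POS for s in inv) == 21
        assert sum(s.ala is AlaStatus.ALA_NEG for s in inv) == 21

    def test_tissue_histogram(self):
        counts = Counter(s.tissue for s in default_inventory())
        assert counts == {
            Tissue.NPL: 2, Tissue.REA: 5, Tissue.INF: 12,
            Tissue.NEC: 7, Tissue.TUM: 16,
        }

    def test_grade_partition(self):
        inv = default_inventory()
        samples = Counter(s.grade for s in inv)
        assert samples == {Grade.LGG: 7, Grade.HGG: 24, Grade.MET: 11}
        patients = Counter()
        for pid in {s.patient_id for s in inv}:
            grade = next(s.grade for s in inv if s.patient_id == pid)
            patients[grade] += 1
        assert patients == {Grade.LGG: 3, Grade.HGG: 14, Grade.MET: 4}

    def test_unique_sample_ids(self):
        ids = [s.sample_id for s in default_inventory()]
        assert len(set(ids)) == len(ids)


class TestDrawSampleLifetime:
    def test_degenerate_quantiles_are_deterministic(self, rng):
        draws = {draw_sample_lifetime(2.0, 2.0, 2.0, rng) for _ in range(20)}
        assert draws == {2.0}

    def test_median_and_iqr_ratio_recovered(self, rng):
        """The fitted lognormal reproduces the target median and quartile ratio.

        A lognormal is symmetric in log space, so it matches the two
        quartiles' ratio q75/q25 exactly while centering on the median.
        """
        draws = np.array(
            [draw_sample_lifetime(11.0, 8.2, 12.9, rng) for _ in range(100_000)]
        )
        assert np.median(draws) == pytest.approx(11.0, rel=0.01)
        ratio = np.percentile(draws, 75) / np.percentile(draws, 25)
        assert ratio == pytest.approx(12.9 / 8.2, rel=0.02)

    def test_censoring_above_median_preserves_median(self, rng):
        clipped = np.array(
            [
                draw_sample_lifetime(11.0, 8.2, 12.9, rng, clip_range_ns=(1.95, 15.95))
                for _ in range(100_000)
            ]
        )
        assert clipped.max() <= 15.95
        assert np.median(clipped) == pytest.approx(11.0, rel=0.01)


def _noiseless_config(**kw):
    defaults = dict(
        noise="none", pixel_jitter_cv=0.0, vessel_fraction=0.0,
        instrument_phase_rad=0.0, instrument_modulation=1.0,
        image_size=64,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestGenerateSample:
    def test_npl_reconstructs_to_drawn_lifetime(self):
        """Noiseless, jitter-free NPL sample: uniform map at the drawn value."""
        config = _noiseless_config(seed=5)
        spec = next(s for s in config.inventory if s.tissue is Tissue.NPL)
        rec = generate_sample(spec, config)
        cal = calibrate(simulate_reference(config), 0.0)
        lt = reconstruct_map(rec.stacks["NADH"], cal)
        inside = lt.tau_ns[rec.mask & lt.valid]
        truth = rec.true_tau_ns["NADH"]
        assert 1.0 < truth < 1.5  # non-pathological NADH near 1.2 ns
        assert np.allclose(inside, truth, rtol=1e-9)

    def test_necrotic_core_has_sub_nanosecond_nadh(self):
        config = _noiseless_config(seed=11)
        spec = next(s for s in config.inventory if s.tissue is Tissue.NEC)
        rec = generate_sample(spec, config)
        cal = calibrate(simulate_reference(config), 0.0)
        lt = reconstruct_map(rec.stacks["NADH"], cal)
        assert np.nanmin(lt.tau_ns[rec.mask & lt.valid]) < 1.0

    def test_vessel_pixels_exceed_nadh_threshold(self):
        config = _noiseless_config(seed=2, vessel_fraction=1.0)
        spec = config.inventory[0]
        rec = generate_sample(spec, config)
        cal = calibrate(simulate_reference(config), 0.0)
        lt = reconstruct_map(rec.stacks["NADH"], cal)
        assert np.nanmax(lt.tau_ns[rec.mask & lt.valid]) > 5.0

    def test_stacks_share_shape_and_mask_non_empty(self):
        config = CohortConfig(image_size=48, seed=1)
        rec = generate_sample(config.inventory[3], config)
        assert rec.stacks["NADH"].shape == rec.stacks["PPIX"].shape == rec.mask.shape
        assert rec.mask.any()


class TestGenerateCohort:
    def test_default_cohort_has_42_records(self):
        config = CohortConfig(image_size=32, seed=0)
        records, manifest = generate_cohort(config)
        assert len(records) == 42
        assert len(manifest) == 42

    def test_same_seed_reproduces_manifest_exactly(self):
        a = generate_cohort(CohortConfig(image_size=32, seed=9))[1]
        b = generate_cohort(CohortConfig(image_size=32, seed=9))[1]
        assert a.equals(b)

    def test_different_seeds_differ_in_data_not_inventory(self):
        a = generate_cohort(CohortConfig(image_size=32, seed=1))[1]
        b = generate_cohort(CohortConfig(image_size=32, seed=2))[1]
        assert list(a["sample_id"]) == list(b["sample_id"])
        assert list(a["tissue"]) == list(b["tissue"])
        assert not np.allclose(a["true_tau_ppix_ns"], b["true_tau_ppix_ns"])

    def test_duplicate_ids_rejected(self):
        config = CohortConfig(image_size=32)
        config.inventory = config.inventory + [config.inventory[0]]
        with pytest.raises(ValueError, match="duplicate"):
            generate_cohort(config)

    def test_ala_mode_npl_keeps_tissue_parameters(self):
        """Non-pathological samples never adopt the ALA-group PPIX lifetime."""
        ala = generate_cohort(CohortConfig(mode="ala", image_size=32, seed=4))[1]
        tissue = generate_cohort(CohortConfig(mode="tissue", image_size=32, seed=4))[1]
        npl = ala["tissue"] == "NPL"
        assert npl.sum() == 2
        # the per-sample rng streams are mode-independent, so NPL draws must
        # coincide exactly between conditioning modes
        assert np.allclose(
            ala.loc[npl, "true_tau_ppix_ns"], tissue.loc[npl, "true_tau_ppix_ns"]
        )
        # while tumor samples do switch distribution
        tum = ala["tissue"] == "TUM"
        assert not np.allclose(
            ala.loc[tum, "true_tau_ppix_ns"], tissue.loc[tum, "true_tau_ppix_ns"]
        )

    def test_infeasible_target_raises(self):
        with pytest.raises(ValueError):
            CohortConfig(ppix_components_ns=(1.0, 2.0))


def test_group_parameter_tables_are_ordered():
    for p in TISSUE_PARAMS.values():
        assert p.nadh_q25_ns <= p.nadh_median_ns <= p.nadh_q75_ns
        assert p.ppix_q25_ns <= p.ppix_median_ns <= p.ppix_q75_ns
    for a in ALA_PARAMS.values():
        assert a.ppix_q25_ns <= a.ppix_median_ns <= a.ppix_q75_ns
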