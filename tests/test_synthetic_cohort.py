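from dataclasses import replace

import numpy as np
import pytest

from cermorph.atlas_io import load_schedule, load_volume, split_atlas_left_right
from cermorph.morphometry import jacobian_determinant
from cermorph.registration import threshold_probability
from cermorph.synthetic_cohort import (
    CohortConfig,
    CohortSizingError,
    PlantedEffect,
    default_effects,
    draw_scan_days,
    effect_core_mask,
    generate_atlas,
    generate_cohort,
    generate_probability_map,
    generate_subject_series,
    local_scaling_field,
    write_cohort,
)


class TestAtlasGeneration:
    def test_requested_label_count(self, small_atlas):
        assert len(small_atlas.symmetric_label_ids) == 35
        assert len(np.unique(small_atlas.labels)) == 36  # + background

    def test_mirror_symmetry_exact(self, small_atlas):
        np.testing.assert_array_equal(small_atlas.labels, small_atlas.labels[::-1])
        np.testing.assert_allclose(
            small_atlas.template, small_atlas.template[::-1], atol=1e-12
        )

    def test_every_label_on_both_sides(self, small_atlas):
        mid = small_atlas.shape[0] // 2
        for lid in small_atlas.symmetric_label_ids:
            m = small_atlas.labels == lid
            assert m[:mid].any() and m[mid:].any()

    def test_single_label_atlas(self, small_config):
        atlas = generate_atlas(replace(small_config, n_labels_symmetric=1))
        assert atlas.symmetric_label_ids == [1]
        np.testing.assert_array_equal(atlas.labels, atlas.labels[::-1])

    def test_grid_too_small_raises(self):
        with pytest.raises(CohortSizingError):
            generate_atlas(CohortConfig(grid_shape=(8, 8, 8)))

    def test_template_zero_outside_structure(self, small_atlas):
        assert np.all(small_atlas.template[small_atlas.labels == 0] == 0)


class TestProbabilityMap:
    def test_values_in_unit_interval(self, small_config, small_pmap):
        assert small_pmap.min() >= 0 and small_pmap.max() <= 1

    def test_threshold_recovers_structure_support(self, small_config, small_atlas,
                                                  small_pmap):
        mask = threshold_probability(small_pmap)
        support = small_atlas.labels > 0
        # agreement away from the boundary shell
        agree = (mask == support).mean()
        assert agree > 0.98


class TestScheduleDrawing:
    def test_days_strictly_increasing_within_horizon(self, small_config, rng):
        for _ in range(200):
            days = draw_scan_days(small_config, rng)
            assert all(b > a for a, b in zip(days, days[1:]))
            assert days[0] >= 1 and days[-1] <= small_config.horizon_days
            assert 2 <= len(days) <= 5

    def test_mean_scan_count_matches_reference(self, rng):
        cfg = CohortConfig()
        counts = [len(draw_scan_days(cfg, rng)) for _ in range(1000)]
        assert 3 <= np.mean(counts) <= 5


class TestSubjectSeries:
    def _quiet_config(self, small_config):
        return replace(
            small_config,
            noise_sd=0.0,
            subject_warp_max_voxels=0.0,
            affine_rot_sd_deg=0.0,
            affine_logscale_sd=0.0,
            affine_shear_sd=0.0,
            affine_shift_sd_voxels=0.0,
        )

    def test_noiseless_identity_scans_equal_template(self, small_config,
                                                     small_split_atlas, rng):
        cfg = self._quiet_config(small_config)
        series, _ = generate_subject_series(
            cfg, small_split_atlas, "s0", 0, [], rng
        )
        for scan in series.scans:
            np.testing.assert_array_equal(scan.volume, small_split_atlas.template)

    def test_intensity_effect_shifts_masked_mean_by_delta(
        self, small_config, small_split_atlas, rng
    ):
        cfg = self._quiet_config(small_config)
        lob = small_split_atlas.split_label_ids[3]
        eff = PlantedEffect("intensity", lob, tuple(range(1, 8)), 6.5)
        series, _ = generate_subject_series(
            cfg, small_split_atlas, "s0", 1, [eff], rng
        )
        mask = small_split_atlas.lobule_mask(lob)
        base = small_split_atlas.template[mask].mean()
        for scan in series.scans:
            assert scan.volume[mask].mean() == pytest.approx(base + 6.5, abs=1e-9)

    def test_effects_on_negative_subject_rejected(self, small_config,
                                                  small_split_atlas, rng):
        eff = PlantedEffect("intensity", 1, (1,), 5.0)
        with pytest.raises(ValueError):
            generate_subject_series(
                small_config, small_split_atlas, "s0", 0, [eff], rng
            )


class TestPlantedDeformation:
    def test_core_jacobian_is_scale_cubed(self, small_split_atlas):
        cores = {
            l: effect_core_mask(small_split_atlas, l).sum()
            for l in small_split_atlas.split_label_ids
        }
        lob = max(cores, key=cores.get)
        s = 1.15
        field = local_scaling_field(small_split_atlas, lob, s)
        jac = jacobian_determinant(field)
        core = effect_core_mask(small_split_atlas, lob)
        # one voxel margin: finite differences straddle the core boundary
        from scipy.ndimage import binary_erosion

        inner = binary_erosion(core, iterations=1)
        assert inner.any()
        np.testing.assert_allclose(jac[inner], s**3, atol=1e-6)

    def test_scale_factor_must_be_positive(self):
        with pytest.raises(ValueError):
            PlantedEffect("deformation", 1, (5,), 0.0)

    def test_month_window_must_be_valid(self):
        with pytest.raises(ValueError):
            PlantedEffect("intensity", 1, (), 5.0)
        with pytest.raises(ValueError):
            PlantedEffect("intensity", 1, (8,), 5.0)


class TestCohort:
    def test_subject_and_outcome_counts(self, small_config):
        series, atlas, truth = generate_cohort(small_config)
        assert len(series) == small_config.n_subjects
        assert sum(s.outcome for s in series) == small_config.n_positive
        assert sum(truth.outcomes.values()) == small_config.n_positive

    def test_fixed_seed_bit_identical(self, small_config):
        s1, _, t1 = generate_cohort(small_config)
        s2, _, t2 = generate_cohort(small_config)
        assert t1.outcomes == t2.outcomes
        for a, b in zip(s1, s2):
            assert a.days == b.days
            for x, y in zip(a.scans, b.scans):
                np.testing.assert_array_equal(x.volume, y.volume)

    def test_no_positive_subjects_is_valid(self, small_config):
        series, _, truth = generate_cohort(replace(small_config, n_positive=0))
        assert sum(s.outcome for s in series) == 0
        assert truth.effects == []

    def test_effects_only_touch_positive_subjects(self, small_config):
        _, _, truth = generate_cohort(small_config)
        for sid, params in truth.scan_params.items():
            if truth.outcomes[sid] == 0:
                assert all(not p["active_effects"] for p in params)

    def test_default_effects_families_and_windows(self, small_split_atlas, rng):
        effs = default_effects(small_split_atlas, rng, noise_sd=4.0)
        fams = {e.family: e for e in effs}
        assert fams["intensity"].month_window == (1, 2, 3)
        assert fams["intensity"].magnitude == pytest.approx(8.0)
        assert fams["deformation"].month_window == (5, 6, 7)
        assert fams["deformation"].magnitude == pytest.approx(1.15)
        assert fams["intensity"].lobule_id != fams["deformation"].lobule_id


class TestWriteCohort:
    def test_round_trip_and_schedule_consistency(self, small_config, tmp_path):
        series, atlas, truth = generate_cohort(small_config)
        manifest = write_cohort(series, atlas, truth, tmp_path, small_config)
        # volume round trip
        s0 = series[0]
        vol, _ = load_volume(manifest["scans"][s0.subject_id][0])
        np.testing.assert_allclose(
            vol, s0.scans[0].volume.astype(np.float32), rtol=1e-6
        )
        # schedule rows == total scans; outcome column consistent
        loaded = load_schedule(tmp_path / "schedule.csv")
        n_scans = sum(len(s.scans) for s in series)
        assert sum(len(s.scans) for s in loaded) == n_scans
        assert sum(s.outcome for s in loaded) == small_config.n_positive
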