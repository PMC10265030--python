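import math

import numpy as np
import pandas as pd
import pytest

from attamech.stats import loglog_ols
from attamech.synthetic import (CohortParams, age_to_brightness,
                                brightness_to_age_days, generate_age_groups,
                                generate_cohort, generate_indentation_trace,
                                generate_leaf_population, generate_shell_phantom,
                                mask_unpaired)


class TestCohort:
    def test_identical_seeds_bit_identical(self):
        a = generate_cohort(CohortParams(seed=42))
        b = generate_cohort(CohortParams(seed=42))
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(generate_cohort(CohortParams(seed=43)))

    def test_noise_free_force_exponent_exact(self):
        params = CohortParams(n_ants=10, seed=1, force_r2=1.0)
        df = generate_cohort(params)
        fit = loglog_ols(df["muscle_volume_mm3"], df["bite_force_mN"])
        assert fit.slope == pytest.approx(1.64, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_params_recover_every_slope(self):
        df = generate_cohort(CohortParams(n_ants=30, seed=2).noise_free())
        for col, slope in (("modulus_GPa", -0.50), ("thickness_mean_um", -0.62)):
            fit = loglog_ols(df["brightness"], df[col])
            assert fit.slope == pytest.approx(slope, abs=1e-9)

    def test_modulus_group_ratio_follows_generating_power_law(self, default_cohort):
        df = default_cohort
        dark = df[df.brightness < 0.20]
        bright = df[df.brightness > 0.35]
        got = dark.modulus_GPa.mean() / bright.modulus_GPa.mean()
        gm = lambda x: np.exp(np.log(x).mean())
        expected = (gm(dark.brightness) / gm(bright.brightness)) ** -0.50
        assert got == pytest.approx(expected, rel=0.05)

    def test_group_means_near_anchors(self, default_cohort):
        df = default_cohort
        foragers = df[df.stage == "forager"]
        bright = df[df.brightness > 0.35]
        # anchors are medians of the generating power laws; lognormal spread
        # lifts arithmetic group means by its convexity factor (~1.2 for force)
        assert 90 < foragers.bite_force_mN.mean() < 140
        assert 0.45 < foragers.muscle_volume_mm3.mean() < 0.62
        assert bright.bite_force_mN.mean() < 10
        assert 10 < foragers.bite_force_mN.mean() / bright.bite_force_mN.mean() < 30
        assert foragers.modulus_GPa.mean() == pytest.approx(7.2, rel=0.12)
        assert foragers.thickness_mean_um.mean() == pytest.approx(31.0, rel=0.12)

    def test_brightness_within_range_and_flags_measured(self):
        df = generate_cohort(CohortParams(n_ants=200, seed=3))
        assert df.brightness.between(0.13, 0.52).all()
        assert (df.filter(like="_flag") == "measured").all().all()
        assert (df.select_dtypes("number").drop(columns="age_d") > 0).all().all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CohortParams(force_r2=0.0).validate()
        with pytest.raises(ValueError):
            CohortParams(brightness_range=(0.5, 0.2)).validate()
        with pytest.raises(ValueError):
            CohortParams(modulus_anchor_GPa=float("nan")).validate()

    def test_mean_exponent_recovery_within_printed_ci(self):
        slopes = [
            loglog_ols(df.muscle_volume_mm3, df.bite_force_mN).slope
            for df in (generate_cohort(CohortParams(n_ants=10, seed=s))
                       for s in range(200))
        ]
        assert 1.07 < np.mean(slopes) < 2.22

    def test_mask_unpaired_sets_missing_flags(self):
        df = mask_unpaired(generate_cohort(CohortParams(seed=4)), seed=0)
        assert (df.modulus_GPa_flag == "measured").sum() == 12
        assert (df.thickness_mean_um_flag == "measured").sum() == 10
        assert df.loc[df.modulus_GPa_flag == "missing", "modulus_GPa"].isna().all()

    def test_age_map_round_trip(self):
        b = age_to_brightness([1.0, 3.0, 5.0])
        assert b[0] == pytest.approx(0.37) and b[2] == pytest.approx(0.24)
        assert np.allclose(brightness_to_age_days(b), [1, 3, 5])

    def test_age_groups_match_decay_anchors(self):
        groups = generate_age_groups(n_per_group=200, seed=0)
        means = {d: v.mean() for d, v in groups}
        assert means[1.0] == pytest.approx(0.37, abs=0.01)
        assert means[5.0] == pytest.approx(0.24, abs=0.01)


class TestPhantoms:
    def test_solid_ball_volume_matches_analytic(self):
        vol = generate_shell_phantom("solid_ball", radius=10)
        assert vol.n_foreground == pytest.approx(4 / 3 * math.pi * 1000, rel=0.05)

    def test_flat_plate_exact_voxel_count(self):
        vol = generate_shell_phantom("flat_plate", thickness=5, extent=64)
        assert vol.n_foreground == 5 * 64 * 64
        assert vol.data.shape == (64, 64, 64)

    def test_cylinder_metadata_and_volume(self):
        vol = generate_shell_phantom("hollow_cylinder", outer_radius=40,
                                     shell_thickness=10, length=100)
        assert vol.meta["true_thickness_px"] == 10
        analytic = math.pi * (40**2 - 30**2) * 100
        assert vol.n_foreground == pytest.approx(analytic, rel=0.05)

    def test_spherical_shell_volume(self):
        vol = generate_shell_phantom("spherical_shell", outer_radius=20,
                                     shell_thickness=6)
        analytic = 4 / 3 * math.pi * (20**3 - 14**3)
        assert vol.n_foreground == pytest.approx(analytic, rel=0.05)

    def test_shell_thicker_than_radius_rejected(self):
        with pytest.raises(ValueError):
            generate_shell_phantom("hollow_cylinder", outer_radius=8,
                                   shell_thickness=9, length=10)

    def test_phantoms_deterministic(self):
        a = generate_shell_phantom("solid_ball", radius=7)
        b = generate_shell_phantom("solid_ball", radius=7)
        assert np.array_equal(a.data, b.data)


class TestIndentationTraces:
    def test_unloading_stiffness_self_consistent(self):
        tr = generate_indentation_trace(modulus_true_GPa=5.0)
        m, alpha, h_f = tr.meta["m"], tr.meta["alpha"], tr.meta["h_f_nm"]
        h_max = tr.displacement_nm.max()
        assert tr.meta["S_uN_per_nm"] == pytest.approx(
            alpha * m * (h_max - h_f) ** (m - 1)
        )

    def test_profile_timing_and_peak(self):
        tr = generate_indentation_trace()
        assert tr.displacement_nm.max() == pytest.approx(300.0)
        assert tr.time_s[-1] == pytest.approx(30.0, abs=0.02)
        hold = (tr.time_s > 5.1) & (tr.time_s < 24.9)
        assert np.ptp(tr.displacement_nm[hold]) == 0
        assert np.ptp(tr.load_uN[hold]) == 0

    def test_noise_seed_reproducible(self):
        a = generate_indentation_trace(noise_sd_uN=1.0, seed=5)
        b = generate_indentation_trace(noise_sd_uN=1.0, seed=5)
        assert np.array_equal(a.load_uN, b.load_uN)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_indentation_trace(modulus_true_GPa=-1)
        with pytest.raises(ValueError):
            generate_indentation_trace(h_f_frac=1.5)


class TestLeafPopulation:
    def test_median_near_82(self):
        pop = generate_leaf_population(n=100_000, seed=0)
        assert np.median(pop.cutting_forces_mN) == pytest.approx(82.0, abs=2.0)

    def test_bounds_hold_for_99_percent(self):
        pop = generate_leaf_population(n=100_000, seed=1)
        outside = (pop.cutting_forces_mN < 7) | (pop.cutting_forces_mN > 828)
        assert outside.mean() <= 0.01

    def test_degenerate_range_is_point_mass(self):
        pop = generate_leaf_population(n=50, median_force_mN=82,
                                       range_bounds_mN=(82, 82), seed=2)
        assert np.all(pop.cutting_forces_mN == 82)

    def test_infeasible_median_rejected(self):
        with pytest.raises(ValueError):
            generate_leaf_population(median_force_mN=5, range_bounds_mN=(7, 828))

    def test_seeded_reproducibility(self):
        a = generate_leaf_population(n=1000, seed=9)
        b = generate_leaf_population(n=1000, seed=9)
        assert np.array_equal(a.cutting_forces_mN, b.cutting_forces_mN)
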