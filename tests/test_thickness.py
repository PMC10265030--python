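import numpy as np
import pytest
from scipy import ndimage

from attamech.synthetic import generate_shell_phantom
from attamech.thickness import (VoxelVolume, distance_transform, local_thickness,
                                section_thickness, summarize_thickness)
from conftest import brute_force_local_thickness


def _random_blob(shape, seed, p=0.25, smooth=1):
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.random(shape), smooth)
    data = field > np.quantile(field, 1 - p)
    data[0] = data[-1] = False
    data[:, 0] = data[:, -1] = False
    data[:, :, 0] = data[:, :, -1] = False
    return data


class TestDistanceTransform:
    def test_plate_centre_distance(self):
        vol = generate_shell_phantom("flat_plate", thickness=5, extent=32)
        d = distance_transform(vol)
        assert d.max() == pytest.approx(3.0)  # centre plane of a 5 px plate

    def test_single_voxel(self):
        data = np.pad(np.ones((1, 1, 1), bool), 2)
        assert distance_transform(VoxelVolume(data)).max() == pytest.approx(1.0)

    def test_solid_ball_max_within_one_voxel_of_radius(self):
        vol = generate_shell_phantom("solid_ball", radius=10)
        assert abs(distance_transform(vol).max() - 10) <= 1.0

    def test_matches_brute_force_nearest_background(self):
        data = _random_blob((10, 10, 10), seed=3)
        d = distance_transform(VoxelVolume(data, voxel_size_um=2.0))
        fg = np.argwhere(data)
        bg = np.argwhere(~data)
        oracle = np.sqrt(((fg[:, None] - bg[None]) ** 2).sum(-1)).min(1) * 2.0
        assert np.allclose(d[tuple(fg.T)], oracle)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            distance_transform(VoxelVolume(np.zeros((4, 4, 4), bool)))


class TestLocalThickness:
    def test_solid_ball_is_its_own_maximal_sphere(self):
        vol = generate_shell_phantom("solid_ball", radius=10)
        tmap = local_thickness(vol)
        vals = tmap.values_um[vol.data]
        assert vals.max() == pytest.approx(20.0)
        assert abs(vals.mean() - 20.0) <= 1.0  # within discretization

    def test_cylinder_phantom_within_one_percent(self):
        vol = generate_shell_phantom("hollow_cylinder", outer_radius=40,
                                     shell_thickness=10, length=100)
        summ = summarize_thickness(local_thickness(vol))
        assert abs(summ.mean_um - 10.0) / 10.0 <= 0.01

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_sphere_oracle(self, seed):
        data = _random_blob((12, 12, 12), seed=seed)
        got = local_thickness(VoxelVolume(data)).values_um
        assert np.allclose(got, brute_force_local_thickness(data))

    def test_oracle_agreement_on_larger_structured_volume(self):
        data = np.zeros((16, 16, 16), bool)
        data[2:14, 2:8, 2:14] = True
        data[4:12, 6:12, 4:12] = True
        got = local_thickness(VoxelVolume(data)).values_um
        assert np.allclose(got, brute_force_local_thickness(data))

    def test_invariant_under_lattice_rotations_and_flips(self):
        data = _random_blob((12, 12, 12), seed=7)
        base = local_thickness(VoxelVolume(data)).values_um
        for k in (1, 2, 3):
            rot = np.rot90(data, k=k, axes=(0, 1))
            got = local_thickness(VoxelVolume(rot)).values_um
            assert np.allclose(got, np.rot90(base, k=k, axes=(0, 1)))
        flip = data[::-1]
        got = local_thickness(VoxelVolume(flip)).values_um
        assert np.allclose(got, base[::-1])

    def test_lower_bound_from_distance_transform(self):
        # integer-radius spheres give thickness >= 2 (EDT - 1) everywhere
        data = _random_blob((14, 14, 14), seed=9)
        vol = VoxelVolume(data)
        tmap = local_thickness(vol).values_um
        edt = distance_transform(vol)
        assert np.all(tmap[data] >= 2 * (edt[data] - 1.0) - 1e-9)

    def test_dilation_never_decreases_thickness(self):
        data = _random_blob((12, 12, 12), seed=13)
        grown = ndimage.binary_dilation(data)
        grown[0] = grown[-1] = False
        grown[:, 0] = grown[:, -1] = False
        grown[:, :, 0] = grown[:, :, -1] = False
        before = local_thickness(VoxelVolume(data)).values_um
        after = local_thickness(VoxelVolume(grown)).values_um
        assert np.all(after[data] >= before[data] - 1e-9)

    def test_anisotropic_voxels_refused(self):
        with pytest.raises(ValueError, match="resample|isotropic"):
            VoxelVolume(np.ones((4, 4, 4), bool), voxel_size_um=(1.0, 1.0, 2.0))

    def test_voxel_size_scales_output(self):
        vol = generate_shell_phantom("flat_plate", thickness=6, extent=24,
                                     voxel_size_um=3.0)
        summ = summarize_thickness(local_thickness(vol))
        assert summ.mean_um == pytest.approx(18.0)


class TestSummaries:
    def test_uniform_plate_has_zero_spread(self):
        vol = generate_shell_phantom("flat_plate", thickness=6, extent=24)
        summ = summarize_thickness(local_thickness(vol))
        assert summ.mean_um == pytest.approx(6.0)
        assert summ.sd_um == 0.0 and summ.cv == 0.0

    def test_two_plate_phantom_volume_weighted_mean(self):
        # two slabs (6 px and 14 px) in one volume -> voxel-weighted mean
        data = np.zeros((40, 20, 20), bool)
        data[4:10] = True    # 6 px slab, full cross-section
        data[20:34] = True   # 14 px slab
        summ = summarize_thickness(local_thickness(VoxelVolume(data)))
        expected = (6 * 6 + 14 * 14) / 20.0  # counts proportional to widths
        assert summ.mean_um == pytest.approx(expected)

    def test_cv_is_sd_over_mean(self):
        vol = generate_shell_phantom("hollow_cylinder", outer_radius=16,
                                     shell_thickness=6, length=30)
        summ = summarize_thickness(local_thickness(vol))
        assert summ.cv == pytest.approx(summ.sd_um / summ.mean_um)


class TestSectionThickness:
    def test_constant_lengths(self):
        pairs = [((0, 0), (10, 0))] * 5
        vals = section_thickness(pairs)
        assert vals.mean() == 10 and vals.std() == 0

    def test_printed_group_ratio(self):
        forager = section_thickness([((0, 0), (14.3, 0))] * 30)
        callow = section_thickness([((0, 0), (6.2, 0))] * 30)
        assert forager.mean() / callow.mean() == pytest.approx(2.3, abs=0.02)

    def test_matches_hand_computed_norms(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2, 3))
        vals = section_thickness(pts)
        for v, (a, b) in zip(vals, pts):
            assert v == pytest.approx(np.sqrt(((a - b) ** 2).sum()))

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            section_thickness([((1, 1), (1, 1))])
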