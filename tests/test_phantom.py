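"""Synthetic phantom generator: geometry rasterisation, initial fields,
ground-truth series, ventricle drift, anisotropic D fields, slicing."""

import numpy as np
import pytest

from gliomafit.geometry import Grid3D, Params
from gliomafit.metrics import visible_volume
from gliomafit.phantom import (
    DFieldSpec2D,
    PhantomSpec,
    drift_ventricles,
    extract_slice,
    make_anisotropic_D_field,
    make_brain_phantom,
    make_initial_field,
    simulate_ground_truth,
)


class TestBrainPhantom:
    def test_zero_ventricles_degenerate_case(self):
        spec = PhantomSpec(ventricles=())
        geom = make_brain_phantom(spec)
        assert not geom.ventricle_mask.any()
        np.testing.assert_array_equal(geom.domain_mask, geom.brain_mask)

    def test_ellipsoid_volume_matches_analytic(self):
        spec = PhantomSpec(
            grid=Grid3D((110, 170, 20)), brain_semiaxes=(5.0, 8.0, 4.0), ventricles=()
        )
        geom = make_brain_phantom(spec)
        analytic = 4.0 / 3.0 * np.pi * 5.0 * 8.0 * 4.0
        voxel = visible_volume(geom.brain_mask, spec.grid)
        assert voxel == pytest.approx(analytic, rel=0.03)

    def test_mirror_symmetry(self):
        grid = Grid3D((48, 48, 16))
        cx, cy, cz = grid.center_mm()
        spec = PhantomSpec(
            grid=grid,
            brain_center=(cx, cy, cz),
            ventricles=(((-0.8, 0.2, 0.3), (0.2, 0.4, 0.8)),),
            seed_center=(cx + 0.9, cy, cz),
        )
        mirrored = PhantomSpec(
            grid=grid,
            brain_center=(cx, cy, cz),
            ventricles=(((0.8, 0.2, 0.3), (0.2, 0.4, 0.8)),),
            seed_center=(cx - 0.9, cy, cz),
        )
        a = make_brain_phantom(spec)
        b = make_brain_phantom(mirrored)
        np.testing.assert_array_equal(b.ventricle_mask, a.ventricle_mask[::-1])
        np.testing.assert_array_equal(b.domain_mask, a.domain_mask[::-1])

    def test_ventricle_outside_brain_rejected(self):
        spec = PhantomSpec(ventricles=(((2.2, 0.0, 0.0), (0.3, 0.3, 0.3)),))
        with pytest.raises(ValueError, match="outside the brain"):
            make_brain_phantom(spec)


class TestInitialField:
    def test_seed_density_is_half_capacity(self):
        spec = PhantomSpec()
        geom = make_brain_phantom(spec)
        field = make_initial_field(geom, spec.resolved_seed_center(), 0.6, 0.5)
        nz = field.values[field.values != 0]
        assert nz.size > 0 and np.all(nz == 0.5)
        assert field.time == 264.0  # day 11

    def test_zero_density_gives_zero_field(self):
        spec = PhantomSpec()
        geom = make_brain_phantom(spec)
        field = make_initial_field(geom, spec.resolved_seed_center(), 0.6, 0.0)
        assert not field.values.any()

    def test_subvoxel_sphere_rasterises_to_one_voxel(self):
        spec = PhantomSpec(ventricles=())
        geom = make_brain_phantom(spec)
        center = tuple((i + 0.5) * h for i, h in zip((24, 24, 8), geom.grid.spacing))
        field = make_initial_field(geom, center, 0.04, 0.5)
        assert (field.values != 0).sum() == 1

    def test_sphere_outside_domain_rejected(self):
        spec = PhantomSpec()
        geom = make_brain_phantom(spec)
        with pytest.raises(ValueError):
            make_initial_field(geom, (0.1, 0.1, 0.1), 0.05, 0.5)


class TestGroundTruth:
    def test_noiseless_masks_equal_thresholded_fields(self, default_phantom):
        from gliomafit.solver3d import threshold_to_mask

        spec, series, history = default_phantom
        for mask, field in zip(series.masks, history):
            np.testing.assert_array_equal(mask, threshold_to_mask(field, spec.threshold))

    def test_monotone_growth_at_published_parameters(self, default_phantom):
        spec, series, _ = default_phantom
        v11 = visible_volume(series.masks[0], spec.grid)
        v25 = visible_volume(series.masks[-1], spec.grid)
        assert v25 > v11
        # day-11 seed in the sub-mm^3 range of the study's tumours
        assert 0.6 <= v11 <= 1.0

    def test_same_seed_reproducible_and_noise_on_shell_only(self):
        spec = PhantomSpec(noise_p=0.3, seed=42, days=(11, 15))
        s1, h1 = simulate_ground_truth(spec)
        s2, _ = simulate_ground_truth(spec)
        for a, b in zip(s1.masks, s2.masks):
            np.testing.assert_array_equal(a, b)
        # flips confined to the one-voxel boundary shell of the clean mask
        from gliomafit.solver3d import threshold_to_mask
        from gliomafit.phantom import _boundary_shell

        clean = threshold_to_mask(h1[1], spec.threshold)
        shell = _boundary_shell(clean, s1.geometry.domain_mask)
        diff = s1.masks[1] ^ clean
        assert diff.any() and not (diff & ~shell).any()

    def test_changing_seed_changes_only_noise(self):
        a, ha = simulate_ground_truth(PhantomSpec(noise_p=0.3, seed=1, days=(11, 15)))
        b, hb = simulate_ground_truth(PhantomSpec(noise_p=0.3, seed=2, days=(11, 15)))
        np.testing.assert_allclose(ha[1].values, hb[1].values)
        assert any((ma ^ mb).any() for ma, mb in zip(a.masks, b.masks))


class TestVentricleDrift:
    def test_zero_drift_identity(self, default_phantom):
        spec, series, _ = default_phantom
        geom = series.geometry
        out = drift_ventricles(geom, (0.0, 0.0, 0.0), 25)
        assert out is geom

    def test_centroid_shift(self, default_phantom):
        spec, series, _ = default_phantom
        geom = series.geometry
        out = drift_ventricles(geom, (0.1, 0.0, 0.0), 21)  # +1.0 mm over 10 days
        c0 = np.argwhere(geom.ventricle_mask).mean(axis=0) * geom.grid.spacing
        c1 = np.argwhere(out.ventricle_mask).mean(axis=0) * geom.grid.spacing
        shift = c1 - c0
        assert shift[0] == pytest.approx(1.0, abs=0.05)
        assert abs(shift[1]) < 0.05 and abs(shift[2]) < 0.25

    def test_drift_then_reverse_recovers_mask(self, default_phantom):
        spec, series, _ = default_phantom
        geom = series.geometry
        fwd = drift_ventricles(geom, (0.1, -0.1, 0.0), 18)
        back = drift_ventricles(fwd, (-0.1, 0.1, 0.0), 18)
        np.testing.assert_array_equal(back.ventricle_mask, geom.ventricle_mask)

    def test_drift_out_of_brain_rejected(self, default_phantom):
        spec, series, _ = default_phantom
        with pytest.raises(ValueError):
            drift_ventricles(series.geometry, (1.0, 0.0, 0.0), 25)


class TestAnisotropicDField:
    domain = np.ones((120, 120), dtype=bool)

    def test_axiswise_left_half_interval(self):
        spec = DFieldSpec2D(seed=5)
        dx, dy = make_anisotropic_D_field(self.domain, spec, mode="axiswise")
        left = dx[:60, :]
        assert left.min() >= 0.0 and left.max() <= 0.2 * spec.eta  # [0, 2224]
        right = dx[60:, :]
        assert right.max() <= 0.05 * spec.eta

    def test_bottom_half_mean_by_lln(self):
        spec = DFieldSpec2D(seed=6)
        _, dy = make_anisotropic_D_field(self.domain, spec, mode="axiswise")
        bottom = dy[:, :60]  # 7200 >= 1e4/2 pixels; mean of U[0.3, 0.5] eta
        assert bottom.mean() == pytest.approx(0.4 * spec.eta, rel=0.02)

    def test_degenerate_intervals_give_constant_field(self):
        spec = DFieldSpec2D(
            eta=1000.0,
            left_horizontal=(0.25, 0.25),
            right_horizontal=(0.25, 0.25),
            top_vertical=(0.25, 0.25),
            bottom_vertical=(0.25, 0.25),
        )
        out = make_anisotropic_D_field(self.domain, spec, mode="quadrant")
        assert np.all(out == 250.0)

    def test_deterministic_given_seed_and_zero_outside_domain(self):
        dom = self.domain.copy()
        dom[:10, :] = False
        spec = DFieldSpec2D(seed=9)
        a = make_anisotropic_D_field(dom, spec, mode="quadrant")
        b = make_anisotropic_D_field(dom, spec, mode="quadrant")
        np.testing.assert_array_equal(a, b)
        assert not a[:10, :].any()

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            DFieldSpec2D(left_horizontal=(0.5, 0.2))


class TestExtractSlice:
    def test_restacking_recovers_volume(self):
        rng = np.random.default_rng(0)
        vol = rng.random((6, 7, 8))
        planes = [extract_slice(vol, "transverse", k)[0] for k in range(8)]
        np.testing.assert_array_equal(np.stack(planes, axis=2), vol)

    def test_in_plane_spacings(self):
        grid = Grid3D((6, 7, 8))
        vol = np.zeros(grid.shape)
        assert extract_slice(vol, "transverse", 0, grid)[1] == (0.1, 0.1)
        assert extract_slice(vol, "sagittal", 0, grid)[1] == (0.1, 0.5)
        assert extract_slice(vol, "coronal", 0, grid)[1] == (0.1, 0.5)

    def test_sagittal_indexing_matches_manual(self):
        rng = np.random.default_rng(1)
        vol = rng.random((6, 7, 8))
        plane, _ = extract_slice(vol, "sagittal", 3)
        np.testing.assert_array_equal(plane, vol[3, :, :])

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            extract_slice(np.zeros((4, 4, 4)), "coronal", 9)
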