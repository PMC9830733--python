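"""Ventilation maps: Jacobian determinant, percentile images, top-p% ROIs,
and deformable registration."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates
from scipy.stats import kstest

from ctvent import (
    DisplacementField,
    GridGeometry,
    PhantomSpec,
    RegistrationParams,
    StructureMask,
    functional_rois,
    generate_patient,
    jacobian_ventilation,
    percentile_normalize,
    register_deformable,
    select_breathing_extremes,
)
from ctvent.phantom import AnalyticField, GaussianBump, VentilationPattern
from ctvent.ventilation import displacement_gradient

from conftest import bumpy_pattern


def _full_mask(geom, label="all"):
    return StructureMask(np.ones(geom.shape, bool), geom, label)


class TestJacobian:
    def test_zero_field_gives_zero_ventilation(self):
        geom = GridGeometry((8, 9, 10), (1.0, 2.0, 3.0))
        fld = DisplacementField(np.zeros((8, 9, 10, 3)), geom)
        vm = jacobian_ventilation(fld, _full_mask(geom))
        np.testing.assert_array_equal(vm.v_jac, 0.0)

    def test_linear_expansion_gives_0331_everywhere(self):
        # u = 0.1 * (x, y, z)  ->  det(1.1 I) - 1 = 0.331; linear fields are
        # differentiated exactly even by the one-sided boundary stencil
        geom = GridGeometry((12, 10, 8), (0.8, 0.8, 5.0), (-5.0, -4.0, -20.0))
        X, Y, Z = np.meshgrid(*geom.axis_coords(), indexing="ij")
        u = 0.1 * np.stack([X, Y, Z], axis=-1)
        vm = jacobian_ventilation(DisplacementField(u, geom), _full_mask(geom))
        np.testing.assert_allclose(vm.v_jac, 0.331, rtol=1e-12)

    def test_matches_brute_force_determinant_oracle(self, rng):
        """The vectorized closed-form 3x3 determinant must agree with a
        per-voxel loop building the full matrix and calling a general
        determinant routine on identical finite differences."""
        geom = GridGeometry((10, 9, 8), (1.0, 1.5, 2.5))
        u = rng.normal(0.0, 0.5, size=(*geom.shape, 3))
        # smooth it a little so the field is physically plausible
        from scipy.ndimage import gaussian_filter

        for c in range(3):
            u[..., c] = gaussian_filter(u[..., c], 1.0)
        fld = DisplacementField(u, geom)
        vm = jacobian_ventilation(fld, _full_mask(geom))

        grad = displacement_gradient(fld)
        expected = np.empty(geom.shape)
        for i in range(geom.shape[0]):
            for j in range(geom.shape[1]):
                for k in range(geom.shape[2]):
                    expected[i, j, k] = (
                        np.linalg.det(np.eye(3) + grad[i, j, k]) - 1.0
                    )
        assert np.max(np.abs(vm.v_jac - expected)) < 1e-10

    def test_finite_differences_converge_quadratically(self):
        """Halving the voxel size must reduce the interior error against
        the closed-form Jacobian by ~4x (second-order central stencil)."""
        fld = AnalyticField(bumpy_pattern(), center_mm=(0.0, 0.0, 0.0))

        def interior_error(spacing):
            n = (32, 32, 32)
            geom = GridGeometry(
                n, spacing, tuple(-(ni - 1) * s / 2 for ni, s in zip(n, spacing))
            )
            sampled = fld.sample_on_grid(geom)
            vm = jacobian_ventilation(sampled, _full_mask(geom))
            exact = fld.jacobian_ventilation(geom)
            err = np.abs(vm.v_jac - exact)
            return err[2:-2, 2:-2, 2:-2].max()

        e_coarse = interior_error((4.0, 4.0, 4.0))
        e_fine = interior_error((2.0, 2.0, 2.0))
        assert e_coarse / e_fine == pytest.approx(4.0, rel=0.35)

    def test_analytic_oracle_on_phantom_grid(self, bumpy_patient):
        p = bumpy_patient
        vm = jacobian_ventilation(p.true_field, p.masks["lungs"])
        exact = p.analytic_field.jacobian_ventilation(p.spec.geometry)
        interior = np.zeros(p.spec.geometry.shape, bool)
        interior[1:-1, 1:-1, 1:-1] = True
        sel = interior & p.masks["lungs"].voxels
        # O(h^2) bound: h_z = 5 mm dominates
        assert np.abs(vm.v_jac - exact)[sel].max() < 5e-3

    def test_mismatched_grids_rejected(self):
        geom = GridGeometry((8, 8, 8), (1, 1, 1))
        other = GridGeometry((8, 8, 8), (2, 2, 2))
        fld = DisplacementField(np.zeros((8, 8, 8, 3)), geom)
        with pytest.raises(ValueError, match="grids"):
            jacobian_ventilation(fld, _full_mask(other))

    def test_volume_change_consistency(self, bumpy_patient):
        """Mean of (1 + v_jac) over the lung equals the deformed-to-original
        lung volume ratio for smooth fields (change of variables)."""
        p = bumpy_patient
        vm = jacobian_ventilation(p.true_field, p.masks["lungs"])
        mean_expansion = (1.0 + vm.v_jac[p.masks["lungs"].voxels]).mean()
        ratio = (
            p.masks["lungs_inhale"].voxel_count / p.masks["lungs"].voxel_count
        )
        assert mean_expansion == pytest.approx(ratio, rel=0.02)


class TestPercentile:
    def _map_from_values(self, values):
        n = len(values)
        geom = GridGeometry((n, 1, 1), (1, 1, 1))
        fld = DisplacementField(np.zeros((n, 1, 1, 3)), geom)
        vm = jacobian_ventilation(fld, _full_mask(geom))
        vm.v_jac = np.asarray(values, float).reshape(n, 1, 1)
        return vm

    def test_distinct_values_rank_scaled_to_100(self, rng):
        values = rng.permutation(10) * 0.05
        vm = percentile_normalize(self._map_from_values(values))
        pct = vm.percentile.ravel()
        assert pct[np.argmax(values)] == pytest.approx(100.0)
        assert pct[np.argmin(values)] == pytest.approx(10.0)

    def test_total_tie_gets_average_rank(self):
        vm = percentile_normalize(self._map_from_values(np.full(8, 0.2)))
        # average rank of 8 tied values is 4.5 -> percentile 56.25
        np.testing.assert_allclose(vm.percentile.ravel(), 100.0 * 4.5 / 8)

    def test_percentiles_uniform_for_distinct_values(self, rng):
        values = rng.normal(size=1000)
        vm = percentile_normalize(self._map_from_values(values))
        stat = kstest(vm.percentile.ravel() / 100.0, "uniform").statistic
        assert stat < 0.05

    def test_empty_mask_rejected(self):
        geom = GridGeometry((4, 4, 4), (1, 1, 1))
        fld = DisplacementField(np.zeros((4, 4, 4, 3)), geom)
        mask = StructureMask(np.zeros(geom.shape, bool), geom, "empty")
        with pytest.raises(ValueError):
            jacobian_ventilation(fld, mask)


class TestFunctionalRois:
    @pytest.fixture(scope="class")
    def vmap(self):
        rng = np.random.default_rng(77)
        n = 1000
        geom = GridGeometry((n, 1, 1), (1, 1, 1))
        fld = DisplacementField(np.zeros((n, 1, 1, 3)), geom)
        vm = jacobian_ventilation(fld, _full_mask(geom, "lungs"))
        vm.v_jac = rng.normal(size=(n, 1, 1))  # distinct values
        return percentile_normalize(vm)

    def test_top_p_counts(self, vmap):
        rois = functional_rois(vmap, (30,))
        assert rois["top30"].voxel_count == 300

    def test_p_100_recovers_lung_mask(self, vmap):
        rois = functional_rois(vmap, (100,))
        np.testing.assert_array_equal(
            rois["top100"].voxels, vmap.lung_mask.voxels
        )

    def test_rois_nested(self, bumpy_patient):
        p = bumpy_patient
        vm = percentile_normalize(
            jacobian_ventilation(p.true_field, p.masks["lungs"])
        )
        rois = functional_rois(vm)
        names = list(rois)
        for a, b in zip(names, names[1:]):
            assert np.all(rois[a].voxels <= rois[b].voxels)

    def test_invalid_threshold_rejected(self, vmap):
        for bad in (0, -5, 101):
            with pytest.raises(ValueError):
                functional_rois(vmap, (bad,))

    def test_requires_percentile_image(self, bumpy_patient):
        vm = jacobian_ventilation(
            bumpy_patient.true_field, bumpy_patient.masks["lungs"]
        )
        with pytest.raises(ValueError, match="percentile"):
            functional_rois(vm)


def test_breathing_extreme_selection():
    geom = GridGeometry((4, 4, 4), (1, 1, 1))
    phases = []
    from ctvent import ImageGrid

    for nvox in (10, 6, 14):  # mid, exhale, inhale
        m = np.zeros(geom.shape, bool)
        m.ravel()[:nvox] = True
        phases.append(
            (ImageGrid(np.zeros(geom.shape), geom), StructureMask(m, geom))
        )
    assert select_breathing_extremes(phases) == (1, 2)


class TestRegistration:
    """B-spline registration recovers the phantom's smooth ground truth."""

    PARAMS = RegistrationParams(
        grid_spacing_mm=30.0,
        shrink_factors=(4, 2),
        smoothing_sigmas=(1.0, 0.5),
        iterations=40,
    )

    @pytest.fixture(scope="class")
    def reg_patient(self):
        spec = PhantomSpec(
            grid_shape=(48, 36, 32),
            spacing_mm=(2.0, 2.0, 3.5),
            ventilation_pattern=VentilationPattern(
                base_expansion=0.04,
                expansion_gradient=(0.0, 0.0, 3e-4),
                bumps=(GaussianBump((-18.0, 0.0, 25.0), 0.07, 25.0),),
            ),
            tumor_center_mm=(-18.0, 0.0, 0.0),
            tumor_radius_mm=7.0,
            noise_sigma_hu=0.0,
            seed=3,
        )
        return generate_patient(spec)

    @pytest.fixture(scope="class")
    def forward_field(self, reg_patient):
        return register_deformable(
            reg_patient.exhale, reg_patient.inhale, self.PARAMS
        )

    def test_self_registration_is_identity(self, reg_patient):
        fld = register_deformable(
            reg_patient.exhale, reg_patient.exhale, self.PARAMS
        )
        in_plane = reg_patient.spec.spacing_mm[0]
        assert fld.magnitude.mean() < 0.1 * in_plane

    def test_recovers_ground_truth_field(self, reg_patient, forward_field):
        epe = np.linalg.norm(
            forward_field.u - reg_patient.true_field.u, axis=-1
        )
        lung = reg_patient.masks["lungs"].voxels
        in_plane = reg_patient.spec.spacing_mm[0]
        assert epe[lung].mean() < in_plane

    def test_swapped_arguments_negate_the_field(self, reg_patient, forward_field):
        """Registering with inhale as fixed yields approximately the inverse
        field: composing the two leaves a small residual."""
        reverse = register_deformable(
            reg_patient.inhale, reg_patient.exhale, self.PARAMS
        )
        geom = reg_patient.spec.geometry
        idx = np.meshgrid(*[np.arange(s) for s in geom.shape], indexing="ij")
        composed = np.zeros_like(forward_field.u)
        coords = [
            idx[a] + forward_field.u[..., a] / geom.spacing[a] for a in range(3)
        ]
        for a in range(3):
            composed[..., a] = map_coordinates(
                reverse.u[..., a], coords, order=1, mode="nearest"
            )
        residual = np.linalg.norm(forward_field.u + composed, axis=-1)
        lung = reg_patient.masks["lungs"].voxels
        in_plane = reg_patient.spec.spacing_mm[0]
        assert residual[lung].mean() < in_plane

    def test_mismatched_grids_rejected(self, reg_patient, default_patient):
        with pytest.raises(ValueError, match="grids"):
            register_deformable(reg_patient.exhale, default_patient.exhale)
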