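"""DVH/DFH metrics, PTV indices, OAR statistics — against brute-force
voxel-loop oracles and closed-form cases."""

import numpy as np
import pytest

from ctvent import (
    DisplacementField,
    GridGeometry,
    ImageGrid,
    StructureMask,
    dfh_metrics,
    dvh_metrics,
    jacobian_ventilation,
    oar_metrics,
    percentile_normalize,
    ptv_indices,
)
from ctvent.dosimetry import lung_domain
from ctvent.ventilation import VentilationMap

GEOM = GridGeometry((12, 10, 8), (1.0, 1.0, 2.0))


def _mask(sel, label="m"):
    return StructureMask(sel, GEOM, label)


def _full():
    return _mask(np.ones(GEOM.shape, bool), "all")


def _vmap_with_weights(weights, mask):
    """VentilationMap whose percentile image is exactly `weights` on mask."""
    fld = DisplacementField(np.zeros((*GEOM.shape, 3)), GEOM)
    vm = jacobian_ventilation(fld, mask)
    pct = np.full(GEOM.shape, np.nan)
    pct[mask.voxels] = weights
    return VentilationMap(v_jac=vm.v_jac, lung_mask=mask, percentile=pct)


class TestDvh:
    def test_uniform_dose(self):
        dose = ImageGrid(np.full(GEOM.shape, 10.0), GEOM)
        r = dvh_metrics(dose, _full())
        assert (r.V5, r.V10, r.V20, r.MLD) == (100.0, 100.0, 0.0, 10.0)

    def test_two_level_dose(self):
        arr = np.zeros(GEOM.shape)
        arr[:6] = 30.0  # exactly half the voxels
        r = dvh_metrics(ImageGrid(arr, GEOM), _full())
        assert (r.V5, r.V10, r.V20, r.MLD) == (50.0, 50.0, 50.0, 15.0)

    def test_matches_brute_force_loop(self, rng):
        arr = rng.uniform(0, 70, size=GEOM.shape)
        sel = rng.random(GEOM.shape) < 0.4
        r = dvh_metrics(ImageGrid(arr, GEOM), _mask(sel))
        vals = [arr[i, j, k] for i, j, k in np.argwhere(sel)]
        for x, got in ((5, r.V5), (10, r.V10), (20, r.V20)):
            expected = 100.0 * sum(v >= x for v in vals) / len(vals)
            assert got == expected
        assert r.MLD == pytest.approx(np.mean(vals), rel=1e-14)

    def test_curve_invariants(self, rng):
        arr = rng.uniform(0, 70, size=GEOM.shape)
        r = dvh_metrics(ImageGrid(arr, GEOM), _full())
        assert r.curve.cum_fraction[0] == 100.0
        assert np.all(np.diff(r.curve.cum_fraction) <= 0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dvh_metrics(
                ImageGrid(np.zeros(GEOM.shape), GEOM),
                _mask(np.zeros(GEOM.shape, bool)),
            )


class TestDfh:
    def test_uniform_weights_reduce_to_dvh(self, rng):
        arr = rng.uniform(0, 70, size=GEOM.shape)
        dose = ImageGrid(arr, GEOM)
        mask = _full()
        vm = _vmap_with_weights(np.full(mask.voxel_count, 3.7), mask)
        dvh = dvh_metrics(dose, mask)
        dfh = dfh_metrics(dose, mask, vm)
        assert dfh.fV5 == pytest.approx(dvh.V5, abs=1e-12)
        assert dfh.fV10 == pytest.approx(dvh.V10, abs=1e-12)
        assert dfh.fV20 == pytest.approx(dvh.V20, abs=1e-12)
        assert dfh.fMLD == pytest.approx(dvh.MLD, rel=1e-12)
        np.testing.assert_allclose(
            dfh.curve.cum_fraction, dvh.curve.cum_fraction, atol=1e-9
        )

    def test_function_concentrated_in_high_dose_region(self):
        arr = np.zeros(GEOM.shape)
        arr[:4] = 25.0
        mask = _full()
        w = np.zeros(mask.voxel_count)
        hot = (arr >= 20)[mask.voxels]
        w[hot] = 1.0
        vm = _vmap_with_weights(w, mask)
        r = dfh_metrics(ImageGrid(arr, GEOM), mask, vm)
        assert r.fV20 == 100.0

    def test_matches_brute_force_weighted_sums(self, rng):
        arr = rng.uniform(0, 70, size=GEOM.shape)
        sel = rng.random(GEOM.shape) < 0.5
        mask = _mask(sel)
        w = rng.uniform(0.1, 5.0, size=mask.voxel_count)
        vm = _vmap_with_weights(w, mask)
        r = dfh_metrics(ImageGrid(arr, GEOM), mask, vm)
        d = arr[sel]
        for x, got in ((5, r.fV5), (10, r.fV10), (20, r.fV20)):
            expected = 100.0 * w[d >= x].sum() / w.sum()
            assert got == pytest.approx(expected, rel=1e-12)
        assert r.fMLD == pytest.approx((w * d).sum() / w.sum(), rel=1e-12)

    def test_raw_positive_weighting_clips_contraction(self, rng):
        arr = rng.uniform(0, 70, size=GEOM.shape)
        mask = _full()
        fld = DisplacementField(np.zeros((*GEOM.shape, 3)), GEOM)
        vm = jacobian_ventilation(fld, mask)
        vm.v_jac = rng.normal(0.0, 0.2, size=GEOM.shape)
        r = dfh_metrics(ImageGrid(arr, GEOM), mask, vm, weighting="raw_positive")
        w = np.clip(vm.v_jac, 0, None)[mask.voxels]
        d = arr[mask.voxels]
        assert r.fV10 == pytest.approx(100.0 * w[d >= 10].sum() / w.sum())

    def test_all_zero_weights_rejected(self):
        mask = _full()
        vm = _vmap_with_weights(np.zeros(mask.voxel_count), mask)
        with pytest.raises(ValueError, match="zero"):
            dfh_metrics(ImageGrid(np.ones(GEOM.shape), GEOM), mask, vm)


class TestPtvIndices:
    def test_perfect_plan(self):
        sel = np.zeros(GEOM.shape, bool)
        sel[4:8, 4:8, 2:6] = True
        arr = np.where(sel, 60.0, 0.0)
        hi, ci, v60 = ptv_indices(ImageGrid(arr, GEOM), _mask(sel, "ptv"))
        assert hi == 0.0
        assert ci == 1.0
        assert v60 == 100.0

    def test_paddick_half_when_isodose_doubles_target(self):
        ptv = np.zeros(GEOM.shape, bool)
        ptv[0:4, :4, :4] = True
        spill = np.zeros(GEOM.shape, bool)
        spill[6:10, :4, :4] = True  # disjoint, same size
        arr = np.where(ptv | spill, 61.0, 0.0)
        _, ci, _ = ptv_indices(ImageGrid(arr, GEOM), _mask(ptv, "ptv"))
        assert ci == pytest.approx(0.5)

    def test_rtog_variant(self):
        ptv = np.zeros(GEOM.shape, bool)
        ptv[0:4, :4, :4] = True
        spill = np.zeros(GEOM.shape, bool)
        spill[6:10, :4, :4] = True
        arr = np.where(ptv | spill, 61.0, 0.0)
        _, ci, _ = ptv_indices(
            ImageGrid(arr, GEOM), _mask(ptv, "ptv"), ci_variant="rtog"
        )
        assert ci == pytest.approx(2.0)

    def test_matches_sorting_oracle(self, rng):
        sel = np.zeros(GEOM.shape, bool)
        sel[3:9, 2:8, 1:7] = True
        arr = rng.uniform(50, 70, size=GEOM.shape)
        hi, ci, v60 = ptv_indices(ImageGrid(arr, GEOM), _mask(sel, "ptv"))
        d = np.sort(arr[sel])
        d2, d50, d98 = (np.percentile(d, q) for q in (98, 50, 2))
        assert hi == pytest.approx((d2 - d98) / d50, rel=1e-12)
        piv = arr >= 60.0
        inter = (piv & sel).sum()
        assert ci == pytest.approx(inter**2 / (sel.sum() * piv.sum()), rel=1e-12)
        assert v60 == pytest.approx(100.0 * inter / sel.sum(), rel=1e-12)

    def test_no_prescription_isodose_warns_and_zeroes_ci(self):
        sel = np.zeros(GEOM.shape, bool)
        sel[:2] = True
        arr = np.full(GEOM.shape, 10.0)
        with pytest.warns(UserWarning, match="prescription"):
            _, ci, v60 = ptv_indices(ImageGrid(arr, GEOM), _mask(sel, "ptv"))
        assert ci == 0.0
        assert v60 == 0.0


class TestOar:
    def test_uniform_heart(self):
        masks = {"heart": _mask(np.ones(GEOM.shape, bool), "heart")}
        r = oar_metrics(ImageGrid(np.full(GEOM.shape, 45.0), GEOM), masks)
        assert r["heart_V45"] == 100.0
        assert r["heart_Dmean"] == 45.0

    def test_cord_hotspot_dmax(self):
        cord = np.zeros(GEOM.shape, bool)
        cord[5, 5, :] = True
        arr = np.full(GEOM.shape, 20.0)
        arr[5, 5, 3] = 40.54
        r = oar_metrics(ImageGrid(arr, GEOM), {"spinal_cord": _mask(cord)})
        assert r["cord_Dmax"] == 40.54

    def test_missing_structure_reported_absent(self):
        r = oar_metrics(ImageGrid(np.zeros(GEOM.shape), GEOM), {})
        assert all(np.isnan(v) for v in r.values())

    def test_matches_brute_force(self, rng):
        arr = rng.uniform(0, 60, size=GEOM.shape)
        masks = {
            "heart": _mask(rng.random(GEOM.shape) < 0.3, "heart"),
            "esophagus": _mask(rng.random(GEOM.shape) < 0.1, "esophagus"),
            "spinal_cord": _mask(rng.random(GEOM.shape) < 0.1, "spinal_cord"),
        }
        r = oar_metrics(ImageGrid(arr, GEOM), masks)
        hv = arr[masks["heart"].voxels]
        assert r["heart_Dmean"] == pytest.approx(hv.mean(), rel=1e-14)
        assert r["heart_V45"] == 100.0 * (hv >= 45).sum() / hv.size
        assert r["esophagus_Dmean"] == pytest.approx(
            arr[masks["esophagus"].voxels].mean(), rel=1e-14
        )
        assert r["cord_Dmax"] == arr[masks["spinal_cord"].voxels].max()


def test_lung_domain_subtraction(default_patient):
    masks = default_patient.masks
    dom = lung_domain(masks, "lung_minus_igtv")
    assert dom.voxel_count == (
        masks["lungs"].voxels & ~masks["igtv"].voxels
    ).sum()
    whole = lung_domain(masks, "whole_lung")
    assert whole.voxel_count == masks["lungs"].voxel_count
    with pytest.raises(ValueError):
        lung_domain(masks, "lung_minus_gtv")
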