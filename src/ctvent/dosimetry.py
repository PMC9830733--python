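"""Dose-volume and dose-function metrics, PTV indices, OAR statistics.

DVH metrics treat every lung voxel equally; DFH metrics weight each voxel
by its ventilation function, so fVx is the percentage of *total lung
function* (not volume) receiving at least x Gy:

    Vx   = 100 * |{v in mask : D(v) >= x}| / |mask|
    fVx  = 100 * sum_{D(v) >= x} w(v) / sum_v w(v)
    MLD  = mean_v D(v)                  fMLD = sum_v w(v) D(v) / sum_v w(v)

With uniform weights the DFH quantities reduce exactly to their DVH
counterparts.  The ">= x" convention makes V0 = 100% hold identically;
on continuously distributed dose it is equivalent to the strict form.

Scalar metrics are always computed exactly from the voxel values; the
cumulative curves (0.1 Gy bins by default) exist only for export/plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import ImageGrid, StructureMask
from .ventilation import VentilationMap

__all__ = [
    "HistogramCurve",
    "DvhResult",
    "DfhResult",
    "dvh_metrics",
    "dfh_metrics",
    "ptv_indices",
    "oar_metrics",
    "lung_domain",
]

WEIGHTING_MODES = ("percentile", "raw_positive")
LUNG_DEFINITIONS = ("lung_minus_igtv", "lung_minus_ptv", "whole_lung")
CI_VARIANTS = ("paddick", "rtog")


@dataclass
class HistogramCurve:
    """Cumulative dose histogram: percent of volume (or function) receiving
    at least each dose level."""

    dose_edges: np.ndarray  # Gy
    cum_fraction: np.ndarray  # %, non-increasing, 100 at 0 Gy

    def as_table(self) -> np.ndarray:
        return np.column_stack([self.dose_edges, self.cum_fraction])


@dataclass
class DvhResult:
    curve: HistogramCurve
    V5: float
    V10: float
    V20: float
    MLD: float


@dataclass
class DfhResult:
    curve: HistogramCurve
    fV5: float
    fV10: float
    fV20: float
    fMLD: float


def _cumulative_curve(dose: np.ndarray, weights: np.ndarray, max_gy: float = 80.0,
                      bin_gy: float = 0.1) -> HistogramCurve:
    edges = np.arange(0.0, max_gy + bin_gy / 2, bin_gy)
    total = weights.sum()
    # fraction of weight at or above each edge
    order = np.argsort(dose)
    sorted_dose = dose[order]
    csum = np.cumsum(weights[order])
    below = np.searchsorted(sorted_dose, edges, side="left")
    w_below = np.where(below > 0, csum[np.clip(below - 1, 0, None)], 0.0)
    cum = 100.0 * (total - w_below) / total
    return HistogramCurve(edges, cum)


def lung_domain(masks: dict[str, StructureMask], mode: str = "lung_minus_igtv") -> StructureMask:
    """Lung evaluation domain for DVH/DFH metrics."""
    if mode not in LUNG_DEFINITIONS:
        raise ValueError(f"unknown lung definition {mode!r}")
    lungs = masks["lungs"]
    sel = lungs.voxels
    if mode == "lung_minus_igtv":
        sel = sel & ~masks["igtv"].voxels
    elif mode == "lung_minus_ptv":
        sel = sel & ~masks["ptv"].voxels
    return StructureMask(sel, lungs.geometry, f"lung({mode})")


def dvh_metrics(dose: ImageGrid, mask: StructureMask) -> DvhResult:
    """Structure-based lung dose-volume metrics V5/V10/V20 (%) and MLD (Gy)."""
    if not dose.geometry.close_to(mask.geometry):
        raise ValueError("dose and mask live on different grids")
    if mask.is_empty():
        raise ValueError(f"mask '{mask.label}' is empty")
    d = dose.data[mask.voxels].astype(float)
    n = d.size
    vx = {x: 100.0 * np.count_nonzero(d >= x) / n for x in (5, 10, 20)}
    curve = _cumulative_curve(d, np.ones_like(d))
    return DvhResult(curve, vx[5], vx[10], vx[20], float(d.mean()))


def _weights(vmap: VentilationMap, mask: StructureMask, weighting: str) -> np.ndarray:
    if weighting not in WEIGHTING_MODES:
        raise ValueError(f"unknown DFH weighting {weighting!r}")
    if weighting == "percentile":
        if vmap.percentile is None:
            raise ValueError("percentile weighting requires a normalized map")
        w = np.nan_to_num(vmap.percentile, nan=0.0)[mask.voxels]
    else:
        w = np.clip(vmap.v_jac, 0.0, None)[mask.voxels]
    return w.astype(float)


def dfh_metrics(
    dose: ImageGrid,
    mask: StructureMask,
    vmap: VentilationMap,
    weighting: str = "percentile",
) -> DfhResult:
    """Ventilation-weighted (dose-function) metrics fV5/fV10/fV20 (%) and
    fMLD (Gy).

    ``weighting`` selects the per-voxel function weight: the percentile
    ventilation value (default — maps are percentile-normalized before
    planning) or the raw positive Jacobian value.
    """
    if not dose.geometry.close_to(mask.geometry):
        raise ValueError("dose and mask live on different grids")
    if mask.is_empty():
        raise ValueError(f"mask '{mask.label}' is empty")
    w = _weights(vmap, mask, weighting)
    total = w.sum()
    if total <= 0:
        raise ValueError("all ventilation weights are zero on the mask")
    d = dose.data[mask.voxels].astype(float)
    fvx = {x: 100.0 * w[d >= x].sum() / total for x in (5, 10, 20)}
    fmld = float((w * d).sum() / total)
    curve = _cumulative_curve(d, w)
    return DfhResult(curve, fvx[5], fvx[10], fvx[20], fmld)


def ptv_indices(
    dose: ImageGrid,
    ptv: StructureMask,
    prescription_gy: float = 60.0,
    ci_variant: str = "paddick",
) -> tuple[float, float, float]:
    """Homogeneity index, conformity index, and PTV V_Rx coverage (%).

    HI is the ICRU-83 form (D2% - D98%) / D50% over the PTV (0 = perfectly
    homogeneous).  CI defaults to the Paddick conformity index
    TV_PIV^2 / (TV * PIV) where TV is the PTV volume, PIV the
    prescription-isodose volume, and TV_PIV their intersection (1 = perfect
    conformity); the RTOG ratio PIV/TV is available as a variant.
    """
    if ci_variant not in CI_VARIANTS:
        raise ValueError(f"unknown CI variant {ci_variant!r}")
    if ptv.is_empty():
        raise ValueError("PTV mask is empty")
    if not dose.geometry.close_to(ptv.geometry):
        raise ValueError("dose and PTV live on different grids")

    d_ptv = dose.data[ptv.voxels].astype(float)
    # Dx% = minimum dose to the hottest x% of the volume
    d2, d50, d98 = np.percentile(d_ptv, [98.0, 50.0, 2.0])
    hi = float((d2 - d98) / d50)

    piv = dose.data >= prescription_gy
    tv = ptv.voxel_count
    n_piv = int(piv.sum())
    inter = int((piv & ptv.voxels).sum())
    v_rx = 100.0 * inter / tv
    if n_piv == 0:
        warnings.warn("no voxel reaches the prescription isodose; CI set to 0",
                      stacklevel=2)
        ci = 0.0
    elif ci_variant == "paddick":
        ci = float(inter**2 / (tv * n_piv))
    else:
        ci = float(n_piv / tv)
    return hi, ci, float(v_rx)


def oar_metrics(dose: ImageGrid, masks: dict[str, StructureMask]) -> dict[str, float]:
    """Organ-at-risk dose statistics: heart Dmean/V45, esophagus Dmean,
    spinal cord Dmax.  A missing structure yields NaN (absent), never 0."""
    out: dict[str, float] = {
        "heart_Dmean": np.nan,
        "heart_V45": np.nan,
        "esophagus_Dmean": np.nan,
        "cord_Dmax": np.nan,
    }
    if "heart" in masks and not masks["heart"].is_empty():
        d = dose.data[masks["heart"].voxels]
        out["heart_Dmean"] = float(d.mean())
        out["heart_V45"] = float(100.0 * np.count_nonzero(d >= 45.0) / d.size)
    if "esophagus" in masks and not masks["esophagus"].is_empty():
        out["esophagus_Dmean"] = float(dose.data[masks["esophagus"].voxels].mean())
    if "spinal_cord" in masks and not masks["spinal_cord"].is_empty():
        out["cord_Dmax"] = float(dose.data[masks["spinal_cord"].voxels].max())
    return out
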