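"""CT-ventilation imaging: registration, Jacobian maps, percentile ROIs.

The pipeline follows the standard 4DCT ventilation recipe: segment the
lungs, pick the peak-exhale and peak-inhale phases, deformably register
them, take the Jacobian determinant of the displacement field as a
ventilation surrogate, and percentile-normalize the map over the lung.

The per-voxel ventilation surrogate is

    V_jac(x, y, z) = det(I + grad u) - 1

where ``u`` is the exhale->inhale displacement in mm.  Positive values mark
local lung expansion on inspiration (ventilated tissue), negative values
local contraction.  ``V_jac > -1`` wherever the deformation is invertible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy.stats import rankdata

from .grids import DisplacementField, GridGeometry, ImageGrid, StructureMask

__all__ = [
    "VentilationMap",
    "RegistrationParams",
    "register_deformable",
    "jacobian_ventilation",
    "percentile_normalize",
    "functional_rois",
    "select_breathing_extremes",
    "displacement_gradient",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (10, 20, 30, 40, 50)


@dataclass
class VentilationMap:
    """Jacobian ventilation values and their percentile image on a lung mask."""

    v_jac: np.ndarray
    lung_mask: StructureMask
    percentile: np.ndarray | None = None  # in [0, 100], NaN outside mask

    def __post_init__(self) -> None:
        if self.v_jac.shape != self.lung_mask.geometry.shape:
            raise ValueError("v_jac shape does not match the grid")

    @property
    def geometry(self) -> GridGeometry:
        return self.lung_mask.geometry


def displacement_gradient(fld: DisplacementField) -> np.ndarray:
    """Displacement gradient tensor, shape (*grid, 3, 3), entry [i, j] =
    d u_i / d x_j; central differences in mm, one-sided at the boundary."""
    spacing = fld.geometry.spacing
    grad = np.empty(fld.geometry.shape + (3, 3), dtype=float)
    for i, comp in enumerate(fld.components()):
        for j in range(3):
            if fld.geometry.shape[j] < 2:
                # single-slice extent: no derivative can be formed; the
                # component is constant along this axis as far as we can tell
                grad[..., i, j] = 0.0
            else:
                grad[..., i, j] = np.gradient(comp, spacing[j], axis=j)
    return grad


def jacobian_ventilation(fld: DisplacementField, lung_mask: StructureMask) -> VentilationMap:
    """Jacobian ventilation map: det(I + grad u) - 1 at every voxel.

    The determinant is expanded in closed form from the nine partial
    derivatives, exactly the 3x3 determinant of the deformation gradient.
    """
    if not fld.geometry.close_to(lung_mask.geometry):
        raise ValueError("field and lung mask live on different grids")
    if lung_mask.is_empty():
        raise ValueError("lung mask is empty")
    g = displacement_gradient(fld)
    a = g[..., 0, 0] + 1.0
    b = g[..., 0, 1]
    c = g[..., 0, 2]
    d = g[..., 1, 0]
    e = g[..., 1, 1] + 1.0
    f = g[..., 1, 2]
    h = g[..., 2, 0]
    i = g[..., 2, 1]
    j = g[..., 2, 2] + 1.0
    det = a * (e * j - f * i) - b * (d * j - f * h) + c * (d * i - e * h)
    return VentilationMap(v_jac=det - 1.0, lung_mask=lung_mask)


def percentile_normalize(vmap: VentilationMap) -> VentilationMap:
    """Convert the ventilation map to a percentile image over lung voxels.

    percentile(v) = 100 * rank(v_jac(v)) / N over the N lung voxels, with
    average ranks for ties; voxels outside the lung are NaN.
    """
    mask = vmap.lung_mask.voxels
    n = int(mask.sum())
    if n == 0:
        raise ValueError("cannot percentile-normalize on an empty lung mask")
    values = vmap.v_jac[mask]
    ranks = rankdata(values, method="average")
    pct = np.full(vmap.v_jac.shape, np.nan)
    pct[mask] = 100.0 * ranks / n
    return VentilationMap(v_jac=vmap.v_jac, lung_mask=vmap.lung_mask, percentile=pct)


def functional_rois(
    vmap: VentilationMap, thresholds=DEFAULT_THRESHOLDS
) -> dict[str, StructureMask]:
    """Top-p% functional lung ROIs from the percentile image.

    The top-p mask contains the lung voxels whose percentile exceeds
    100 - p, so with N distinct values it holds exactly floor(p% of N)
    voxels, and the masks are nested: top10 within top20 ... within top50.
    """
    if vmap.percentile is None:
        raise ValueError("percentile image not computed; call percentile_normalize")
    rois: dict[str, StructureMask] = {}
    for p in thresholds:
        if not (0 < p <= 100):
            raise ValueError(f"threshold {p} outside (0, 100]")
        sel = vmap.lung_mask.voxels & (
            np.nan_to_num(vmap.percentile, nan=-np.inf) > 100.0 - p
        )
        rois[f"top{p:g}"] = StructureMask(sel, vmap.geometry, f"top{p:g}")
    return rois


def select_breathing_extremes(
    phases: list[tuple[ImageGrid, StructureMask]],
) -> tuple[int, int]:
    """Identify (peak-exhale, peak-inhale) phase indices by lung-mask volume:
    exhale is the phase of minimum lung volume, inhale the maximum."""
    if len(phases) < 2:
        raise ValueError("need at least two phases")
    volumes = [m.volume_mm3 for _, m in phases]
    return int(np.argmin(volumes)), int(np.argmax(volumes))


# ---------------------------------------------------------------------------
# Deformable registration (pluggable; any precomputed DisplacementField on
# the fixed grid can be substituted for the output of this function)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistrationParams:
    """Deterministic multi-resolution B-spline registration settings."""

    grid_spacing_mm: float = 30.0
    shrink_factors: tuple[int, ...] = (2, 1)
    smoothing_sigmas: tuple[float, ...] = (1.0, 0.0)
    iterations: int = 50
    convergence_tol: float = 1e-6


def _to_sitk(img: ImageGrid) -> sitk.Image:
    # our arrays are (x, y, z); SimpleITK's numpy bridge expects (z, y, x)
    im = sitk.GetImageFromArray(np.ascontiguousarray(img.data.T, dtype=np.float64))
    im.SetSpacing(tuple(float(s) for s in img.geometry.spacing))
    im.SetOrigin(tuple(float(o) for o in img.geometry.origin))
    return im


def register_deformable(
    fixed: ImageGrid,
    moving: ImageGrid,
    params: RegistrationParams | None = None,
) -> DisplacementField:
    """B-spline deformable registration of ``moving`` onto ``fixed``.

    Returns the dense displacement field u(x) such that
    ``moving(x + u(x)) ~= fixed(x)`` — with fixed = exhale and moving =
    inhale this is exactly the exhale->inhale convention of the ventilation
    map.  Fully deterministic: mean-squares metric on the full voxel set,
    LBFGS-B optimizer, no stochastic sampling.
    """
    if not fixed.geometry.close_to(moving.geometry):
        raise ValueError("fixed and moving images live on different grids")
    params = params or RegistrationParams()

    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)

    extent = [
        sz * sp for sz, sp in zip(fixed.geometry.shape, fixed.geometry.spacing)
    ]
    mesh = [max(1, int(round(e / params.grid_spacing_mm))) for e in extent]
    tx = sitk.BSplineTransformInitializer(f_img, mesh)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=params.convergence_tol,
        numberOfIterations=params.iterations,
    )
    reg.SetInitialTransform(tx, inPlace=True)
    reg.SetShrinkFactorsPerLevel(list(params.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(params.smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    final_tx = reg.Execute(f_img, m_img)

    stop = reg.GetOptimizerStopConditionDescription()
    metric = reg.GetMetricValue()
    converged = "tolerance reached" in stop.lower() or "converge" in stop.lower()
    if not converged:
        log.warning(
            "registration did not report convergence (%s); final metric %.4g",
            stop,
            metric,
        )
    else:
        log.info("registration converged; final metric %.4g", metric)

    to_field = sitk.TransformToDisplacementFieldFilter()
    to_field.SetReferenceImage(f_img)
    disp = sitk.GetArrayFromImage(to_field.Execute(final_tx))  # (z, y, x, 3)
    u = np.ascontiguousarray(np.transpose(disp, (2, 1, 0, 3)))  # -> (x, y, z, 3)
    return DisplacementField(u, fixed.geometry)
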