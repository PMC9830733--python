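"""Synthetic thorax phantom: breathing deformation, structures, and dose grids.

The phantom supplies everything a functional-avoidance analysis consumes —
a peak-exhale/peak-inhale CT-like pair, the exact displacement field that
relates them, structure masks (lungs, IGTV/CTV/PTV, heart, esophagus,
spinal cord), and one emulated dose grid per planning strategy — with the
crucial property that the deformation is *analytic*: its Jacobian, and
hence the ground-truth ventilation at every voxel, is known in closed form.

Deformation model
-----------------
The exhale->inhale displacement is a sum of a spatially graded expansion
about the thorax center ``c`` and radial Gaussian "breathing units":

    u(x) = (a0 + g.(x - c)) (x - c)  +  sum_k A_k exp(-|x-p_k|^2 / 2 s_k^2) (x - p_k)

The graded term produces the smooth ventilation heterogeneity seen in 4DCT
ventilation maps (a dominant gradient direction), and the radial bumps add
localized hyper- or hypo-ventilating regions (a negative-amplitude bump at
the tumor models the ventilation defect of an airway-obstructing mass).
The displacement gradient is

    grad u = s(x) I + (x - c) (x) g  +  sum_k A_k e_k [ I - (x-p_k)(x-p_k)^T / s_k^2 ]

so ``det(I + grad u) - 1`` — the Jacobian ventilation — is available
exactly, without finite differences, and serves as the oracle for the
ventilation module.

Dose model
----------
Plans are emulated, not optimized: the prescription (60 Gy in 30 fractions)
is delivered to the PTV with a sigmoidal distance falloff outside it;
functional strategies multiply dose by ``avoidance_factor`` inside the
avoidance ROI (excluding the PTV, so target coverage is never traded away).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import expand_margin
from .grids import DisplacementField, GridGeometry, ImageGrid, StructureMask

__all__ = [
    "GaussianBump",
    "VentilationPattern",
    "LungGeometry",
    "PhantomSpec",
    "DosePhantomSpec",
    "PhantomPatient",
    "PlanDoseSet",
    "CohortPatient",
    "generate_patient",
    "generate_plan_doses",
    "generate_cohort",
    "STRATEGIES",
]

#: Planning strategies, one anatomical plan plus five functional plans that
#: avoid the top 10..50% ventilated lung.
STRATEGIES = ("anatomical", "top10", "top20", "top30", "top40", "top50")

HU_SOFT_TISSUE = 40.0
HU_LUNG = -800.0


@dataclass(frozen=True)
class GaussianBump:
    """Radial expansion unit: u = amplitude * exp(-r^2/2 sigma^2) * (x - center)."""

    center_mm: tuple[float, float, float]
    amplitude: float
    sigma_mm: float

    def __post_init__(self) -> None:
        if self.sigma_mm <= 0:
            raise ValueError("bump sigma must be positive")


@dataclass(frozen=True)
class VentilationPattern:
    """Parameters of the smooth spatial expansion field.

    ``base_expansion`` is the dimensionless isotropic expansion coefficient
    at the thorax center; ``expansion_gradient`` (1/mm) grades it along a
    direction, creating the dominant ventilation gradient; ``bumps`` add
    localized hyper-/hypo-ventilation.
    """

    base_expansion: float = 0.05
    expansion_gradient: tuple[float, float, float] = (0.0, 0.0, 4.0e-4)
    bumps: tuple[GaussianBump, ...] = ()


@dataclass(frozen=True)
class LungGeometry:
    """Two ellipsoidal lungs, centers and semi-axes in mm."""

    right_center: tuple[float, float, float] = (-18.0, 0.0, 0.0)
    right_semiaxes: tuple[float, float, float] = (13.0, 16.0, 70.0)
    left_center: tuple[float, float, float] = (18.0, 0.0, 0.0)
    left_semiaxes: tuple[float, float, float] = (13.0, 16.0, 70.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic patient.

    The default grid emulates the acquisition geometry of thoracic 4DCT
    protocols (0.8 x 0.8 mm pixels, 5 mm slices) on a miniature thorax
    sized for fast, exhaustive testing.
    """

    grid_shape: tuple[int, int, int] = (96, 72, 40)
    spacing_mm: tuple[float, float, float] = (0.8, 0.8, 5.0)
    lung_geometry: LungGeometry = field(default_factory=LungGeometry)
    tumor_center_mm: tuple[float, float, float] = (-18.0, 0.0, 10.0)
    tumor_radius_mm: float = 8.0
    ventilation_pattern: VentilationPattern = field(default_factory=VentilationPattern)
    noise_sigma_hu: float = 10.0
    texture_amplitude_hu: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor radius must be positive")

    @property
    def geometry(self) -> GridGeometry:
        """Grid centered on the world origin (voxel centers symmetric)."""
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)
        origin = -extent / 2.0 + np.asarray(self.spacing_mm) / 2.0
        return GridGeometry(tuple(self.grid_shape), tuple(self.spacing_mm), tuple(origin))

    @property
    def thorax_center_mm(self) -> np.ndarray:
        lg = self.lung_geometry
        return (np.asarray(lg.right_center) + np.asarray(lg.left_center)) / 2.0


@dataclass(frozen=True)
class DosePhantomSpec:
    """Parameters of the emulated dose distribution."""

    prescription_Gy: float = 60.0
    n_fractions: int = 30
    falloff_mm: float = 12.0
    avoidance_factor: float = 0.5
    peak_scale: float = 1.05  # hotspot scale inside PTV, typical of HT plans
    noise_sigma_Gy: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.avoidance_factor <= 1.0):
            raise ValueError("avoidance_factor must lie in [0, 1]")
        if self.prescription_Gy <= 0 or self.falloff_mm <= 0:
            raise ValueError("prescription and falloff must be positive")


# ---------------------------------------------------------------------------
# Analytic displacement field
# ---------------------------------------------------------------------------


class AnalyticField:
    """Closed-form displacement field of a :class:`PhantomSpec`.

    Evaluates u(x) and grad u(x) exactly at arbitrary world points, and the
    exact Jacobian ventilation det(I + grad u) - 1 on the grid.
    """

    def __init__(self, pattern: VentilationPattern, center_mm) -> None:
        self.pattern = pattern
        self.center = np.asarray(center_mm, dtype=float)

    def _scale(self, X, Y, Z):
        g = self.pattern.expansion_gradient
        return (
            self.pattern.base_expansion
            + g[0] * (X - self.center[0])
            + g[1] * (Y - self.center[1])
            + g[2] * (Z - self.center[2])
        )

    def displacement(self, X, Y, Z) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """u components at broadcastable world-coordinate arrays (mm)."""
        s = self._scale(X, Y, Z)
        dx, dy, dz = X - self.center[0], Y - self.center[1], Z - self.center[2]
        ux, uy, uz = s * dx, s * dy, s * dz
        for b in self.pattern.bumps:
            bx, by, bz = X - b.center_mm[0], Y - b.center_mm[1], Z - b.center_mm[2]
            e = b.amplitude * np.exp(-(bx**2 + by**2 + bz**2) / (2.0 * b.sigma_mm**2))
            ux = ux + e * bx
            uy = uy + e * by
            uz = uz + e * bz
        return ux, uy, uz

    def gradient(self, X, Y, Z) -> np.ndarray:
        """Exact displacement gradient, shape broadcast(X,Y,Z) + (3, 3);
        entry [i, j] = d u_i / d x_j."""
        X, Y, Z = np.broadcast_arrays(np.asarray(X, float), np.asarray(Y, float), np.asarray(Z, float))
        s = self._scale(X, Y, Z)
        g = np.asarray(self.pattern.expansion_gradient, float)
        d = np.stack([X - self.center[0], Y - self.center[1], Z - self.center[2]], axis=-1)
        eye = np.eye(3)
        grad = s[..., None, None] * eye + d[..., :, None] * g[None, :]
        for b in self.pattern.bumps:
            r = np.stack(
                [X - b.center_mm[0], Y - b.center_mm[1], Z - b.center_mm[2]], axis=-1
            )
            e = b.amplitude * np.exp(-np.sum(r**2, axis=-1) / (2.0 * b.sigma_mm**2))
            outer = r[..., :, None] * r[..., None, :] / b.sigma_mm**2
            grad = grad + e[..., None, None] * (eye - outer)
        return grad

    def jacobian_ventilation(self, geometry: GridGeometry) -> np.ndarray:
        """Exact det(I + grad u) - 1 at every voxel center."""
        X, Y, Z = np.meshgrid(*geometry.axis_coords(), indexing="ij")
        J = self.gradient(X, Y, Z) + np.eye(3)
        return np.linalg.det(J) - 1.0

    def sample_on_grid(self, geometry: GridGeometry) -> DisplacementField:
        X, Y, Z = geometry.meshgrid()
        ux, uy, uz = self.displacement(X, Y, Z)
        shape = geometry.shape
        u = np.stack(
            [np.broadcast_to(c, shape) for c in (ux, uy, uz)], axis=-1
        ).astype(float)
        return DisplacementField(u, geometry)

    def invert(self, X, Y, Z, n_iter: int = 30) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Solve x + u(x) = y by fixed-point iteration (contraction for the
        small displacement gradients the phantom guarantees)."""
        x, y, z = np.array(X, float), np.array(Y, float), np.array(Z, float)
        x, y, z = np.broadcast_arrays(x, y, z)
        px, py, pz = x.copy(), y.copy(), z.copy()
        for _ in range(n_iter):
            ux, uy, uz = self.displacement(px, py, pz)
            px, py, pz = x - ux, y - uy, z - uz
        return px, py, pz


# ---------------------------------------------------------------------------
# Anatomy
# ---------------------------------------------------------------------------


def _ellipsoid_membership(X, Y, Z, center, semiaxes) -> np.ndarray:
    q = (
        ((X - center[0]) / semiaxes[0]) ** 2
        + ((Y - center[1]) / semiaxes[1]) ** 2
        + ((Z - center[2]) / semiaxes[2]) ** 2
    )
    return q <= 1.0


def _sphere_membership(X, Y, Z, center, radius) -> np.ndarray:
    return (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius**2


class _Anatomy:
    """Analytic exhale-frame anatomy: membership and intensity at arbitrary
    world points, so the inhale image can be sampled exactly through the
    inverse deformation with no grid interpolation."""

    def __init__(self, spec: PhantomSpec) -> None:
        self.spec = spec

    def lungs(self, X, Y, Z) -> np.ndarray:
        lg = self.spec.lung_geometry
        return _ellipsoid_membership(
            X, Y, Z, lg.right_center, lg.right_semiaxes
        ) | _ellipsoid_membership(X, Y, Z, lg.left_center, lg.left_semiaxes)

    def tumor(self, X, Y, Z) -> np.ndarray:
        return _sphere_membership(
            X, Y, Z, self.spec.tumor_center_mm, self.spec.tumor_radius_mm
        )

    def intensity(self, X, Y, Z) -> np.ndarray:
        """Two-compartment HU plus a smooth sinusoidal parenchymal texture
        (gives the registration interior signal; no claim of CT realism)."""
        lung = self.lungs(X, Y, Z)
        tumor = self.tumor(X, Y, Z)
        img = np.where(lung & ~tumor, HU_LUNG, HU_SOFT_TISSUE)
        a = self.spec.texture_amplitude_hu
        if a > 0:
            tex = (
                a
                * np.sin(2 * np.pi * X / 23.0)
                * np.sin(2 * np.pi * Y / 19.0)
                * np.sin(2 * np.pi * Z / 41.0)
            )
            img = img + np.where(lung & ~tumor, tex, 0.0)
        return np.asarray(img, dtype=float)


# ---------------------------------------------------------------------------
# Patient generation
# ---------------------------------------------------------------------------


@dataclass
class PhantomPatient:
    """One generated patient: image pair, ground-truth field, masks."""

    exhale: ImageGrid
    inhale: ImageGrid
    true_field: DisplacementField
    masks: dict[str, StructureMask]
    spec: PhantomSpec

    @property
    def analytic_field(self) -> AnalyticField:
        return AnalyticField(self.spec.ventilation_pattern, self.spec.thorax_center_mm)

    def __iter__(self):
        # allow tuple-style unpacking (exhale, inhale, true_field, masks)
        return iter((self.exhale, self.inhale, self.true_field, self.masks))


def _validate_geometry(spec: PhantomSpec) -> None:
    geom = spec.geometry
    lo = np.asarray(geom.origin)
    hi = lo + (np.asarray(geom.shape) - 1) * np.asarray(geom.spacing)
    c = np.asarray(spec.tumor_center_mm)
    if np.any(c - spec.tumor_radius_mm < lo) or np.any(c + spec.tumor_radius_mm > hi):
        raise ValueError(
            f"degenerate geometry: tumor (center {tuple(c)}, radius "
            f"{spec.tumor_radius_mm} mm) extends outside the grid"
        )
    lg = spec.lung_geometry
    inside = False
    for center, semi in (
        (lg.right_center, lg.right_semiaxes),
        (lg.left_center, lg.left_semiaxes),
    ):
        q = sum(((c[i] - center[i]) / semi[i]) ** 2 for i in range(3))
        # inside or abutting: tumor center within ~1.2x the ellipsoid
        if q <= 1.2:
            inside = True
    if not inside:
        raise ValueError(
            "degenerate geometry: tumor center lies neither inside nor "
            "abutting a lung"
        )


def generate_patient(spec: PhantomSpec) -> PhantomPatient:
    """Build one synthetic patient from an analytic deformation.

    The exhale image is evaluated analytically on the grid; the inhale
    image is the pushforward of the same anatomy through the deformation
    phi(x) = x + u(x), sampled by inverting phi at each inhale voxel center
    (fixed-point iteration on the analytic field, exact up to iteration
    tolerance — no grid interpolation enters the ground truth).
    """
    _validate_geometry(spec)
    geom = spec.geometry
    anatomy = _Anatomy(spec)
    fld = AnalyticField(spec.ventilation_pattern, spec.thorax_center_mm)

    # invertibility guard: the analytic Jacobian must stay positive
    vjac = fld.jacobian_ventilation(geom)
    if (1.0 + vjac).min() <= 0.05:
        raise ValueError(
            "ventilation pattern too strong: deformation is (near-)singular, "
            f"min det(I+grad u) = {(1.0 + vjac).min():.3f}"
        )

    X, Y, Z = geom.meshgrid()
    exhale_arr = np.broadcast_to(anatomy.intensity(X, Y, Z), geom.shape).copy()

    Xd, Yd, Zd = np.meshgrid(*geom.axis_coords(), indexing="ij")
    xi, yi, zi = fld.invert(Xd, Yd, Zd)
    inhale_arr = anatomy.intensity(xi, yi, zi)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma_hu > 0:
        # one shared texture-noise realization: a zero deformation must map
        # the exhale image onto itself voxelwise
        noise = rng.normal(0.0, spec.noise_sigma_hu, size=geom.shape)
        exhale_arr = exhale_arr + noise
        inhale_arr = inhale_arr + noise

    lungs_ex = np.broadcast_to(anatomy.lungs(X, Y, Z), geom.shape)
    tumor_ex = np.broadcast_to(anatomy.tumor(X, Y, Z), geom.shape)
    lungs_in = anatomy.lungs(xi, yi, zi)

    masks: dict[str, StructureMask] = {}
    masks["lungs"] = StructureMask(lungs_ex.copy(), geom, "lungs")
    masks["lungs_inhale"] = StructureMask(lungs_in, geom, "lungs_inhale")
    masks["igtv"] = StructureMask(tumor_ex.copy(), geom, "igtv")
    # GTV -> CTV -> PTV margin recipe: 5 mm isotropic, then 5 mm again
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        masks["ctv"] = expand_margin(masks["igtv"], 5.0, label="ctv")
        masks["ptv"] = expand_margin(masks["ctv"], 5.0, label="ptv")

    masks["heart"] = StructureMask(
        np.broadcast_to(
            _ellipsoid_membership(X, Y, Z, (4.0, -8.0, -25.0), (11.0, 9.0, 28.0)),
            geom.shape,
        ).copy(),
        geom,
        "heart",
    )
    eso = (Xd - 0.0) ** 2 + (Yd - 4.0) ** 2 <= 3.5**2
    masks["esophagus"] = StructureMask(eso, geom, "esophagus")
    cord = (Xd - 0.0) ** 2 + (Yd - 20.0) ** 2 <= 4.0**2
    masks["spinal_cord"] = StructureMask(cord, geom, "spinal_cord")

    return PhantomPatient(
        exhale=ImageGrid(exhale_arr, geom),
        inhale=ImageGrid(np.asarray(inhale_arr, float), geom),
        true_field=fld.sample_on_grid(geom),
        masks=masks,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Dose grids
# ---------------------------------------------------------------------------


@dataclass
class PlanDoseSet:
    """Dose grids keyed by planning strategy."""

    doses: dict[str, ImageGrid]
    dose_spec: DosePhantomSpec

    def __getitem__(self, strategy: str) -> ImageGrid:
        return self.doses[strategy]

    @property
    def strategies(self) -> tuple[str, ...]:
        return tuple(self.doses)


def generate_plan_doses(
    masks: dict[str, StructureMask],
    dose_spec: DosePhantomSpec,
    strategies=STRATEGIES,
    avoidance_rois: dict[str, StructureMask] | None = None,
) -> PlanDoseSet:
    """Emulate one dose grid per planning strategy.

    The anatomical strategy delivers ``peak_scale x prescription`` inside
    the PTV with a sigmoidal falloff in distance-to-PTV; each functional
    strategy multiplies the anatomical dose by ``avoidance_factor`` inside
    its avoidance ROI minus the PTV.  With ``avoidance_factor = 1`` every
    functional grid equals the anatomical grid exactly.
    """
    if "ptv" not in masks:
        raise ValueError("masks must include 'ptv'")
    ptv = masks["ptv"]
    geom = ptv.geometry
    avoidance_rois = avoidance_rois or {}

    for name, roi in avoidance_rois.items():
        if roi.voxels.all():
            raise ValueError(
                f"avoidance ROI '{name}' covers the whole grid; no dose can "
                "be delivered anywhere"
            )

    dist = ndimage.distance_transform_edt(~ptv.voxels, sampling=geom.spacing)
    peak = dose_spec.peak_scale * dose_spec.prescription_Gy
    steep = dose_spec.falloff_mm / 4.0
    base = peak / (1.0 + np.exp((dist - dose_spec.falloff_mm) / steep))
    rng = np.random.default_rng(dose_spec.seed)
    if dose_spec.noise_sigma_Gy > 0:
        base = base + rng.normal(0.0, dose_spec.noise_sigma_Gy, size=geom.shape)
    base = np.clip(base, 0.0, None)

    v_rx = (base[ptv.voxels] >= dose_spec.prescription_Gy).mean() * 100.0
    if v_rx < 95.0:
        raise RuntimeError(
            f"emulated plan covers only {v_rx:.1f}% of the PTV at prescription"
        )

    doses: dict[str, ImageGrid] = {}
    for strat in strategies:
        if strat == "anatomical":
            doses[strat] = ImageGrid(base.copy(), geom)
            continue
        if strat not in avoidance_rois:
            raise ValueError(f"functional strategy '{strat}' needs an avoidance ROI")
        roi = avoidance_rois[strat]
        factor = np.ones(geom.shape)
        factor[roi.voxels & ~ptv.voxels] = dose_spec.avoidance_factor
        doses[strat] = ImageGrid(base * factor, geom)
    return PlanDoseSet(doses, dose_spec)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortPatient:
    patient_id: str
    scenario: str  # "benefit" | "non_benefit"
    spec: PhantomSpec


def _patient_spec(scenario: str, rng: np.random.Generator, seed: int) -> PhantomSpec:
    """One randomized patient of a scenario.

    Benefit patients carry large tumors whose surroundings are highly
    ventilated (expansion gradient toward the tumor, hyper-ventilating bump
    abutting the PTV); non-benefit patients carry small tumors far from the
    ventilation peak (gradient away from the tumor, bump in the opposite
    lung) plus a peritumoral ventilation defect.  This mirrors the clinical
    observation that tumor size and the distance between PTV and
    high-function lung separate the two groups.
    """
    if scenario == "benefit":
        radius = float(rng.uniform(9.0, 12.0))
        tz = float(rng.uniform(5.0, 20.0))
        tumor_center = (-18.0, float(rng.uniform(-3.0, 3.0)), tz)
        grad_z = float(rng.uniform(3.0e-4, 5.0e-4))  # more expansion toward +z
        bump = GaussianBump(
            center_mm=(-18.0, 0.0, tz + radius + 12.0),
            amplitude=float(rng.uniform(0.07, 0.10)),
            sigma_mm=float(rng.uniform(22.0, 30.0)),
        )
        defect = GaussianBump(
            center_mm=tumor_center, amplitude=-0.03, sigma_mm=radius + 4.0
        )
        pattern = VentilationPattern(
            base_expansion=0.05,
            expansion_gradient=(0.0, 0.0, grad_z),
            bumps=(bump, defect),
        )
    elif scenario == "non_benefit":
        radius = float(rng.uniform(4.0, 6.0))
        tz = float(rng.uniform(42.0, 52.0))
        tumor_center = (-18.0, float(rng.uniform(-3.0, 3.0)), tz)
        grad_z = float(rng.uniform(-5.0e-4, -3.0e-4))  # expansion away from tumor
        bump = GaussianBump(
            center_mm=(18.0, 0.0, float(rng.uniform(-60.0, -45.0))),
            amplitude=float(rng.uniform(0.07, 0.10)),
            sigma_mm=float(rng.uniform(22.0, 30.0)),
        )
        defect = GaussianBump(
            center_mm=tumor_center, amplitude=-0.06, sigma_mm=radius + 22.0
        )
        pattern = VentilationPattern(
            base_expansion=0.05,
            expansion_gradient=(0.0, 0.0, grad_z),
            bumps=(bump, defect),
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return PhantomSpec(
        tumor_center_mm=tumor_center,
        tumor_radius_mm=radius,
        ventilation_pattern=pattern,
        seed=seed,
    )


def generate_cohort(
    n: int, scenario: str = "mixed", seed: int = 0
) -> list[CohortPatient]:
    """Generate a reproducible cohort of patient specs.

    ``scenario`` is ``"benefit"``, ``"non_benefit"``, or ``"mixed"``
    (alternating, starting with benefit).  Same ``(n, scenario, seed)``
    yields a bit-identical cohort.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 patients")
    if scenario not in ("benefit", "non_benefit", "mixed"):
        raise ValueError(f"unknown scenario {scenario!r}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    patients = []
    for i, child in enumerate(children):
        scen = scenario
        if scenario == "mixed":
            scen = "benefit" if i % 2 == 0 else "non_benefit"
        rng = np.random.default_rng(child)
        patient_seed = int(rng.integers(0, 2**31 - 1))
        spec = _patient_spec(scen, rng, patient_seed)
        patients.append(CohortPatient(f"P{i:03d}", scen, spec))
    return patients
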