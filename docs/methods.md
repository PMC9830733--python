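# Methods

## Ventilation model

The ventilation surrogate is the Jacobian determinant of the
exhale→inhale displacement field minus one:

```
V_jac(x, y, z) = det(I + ∇u) − 1,
```

with the nine partials estimated by central differences in physical
millimetres (one-sided at the volume boundary, zero where an axis has a
single slice). The field convention is fixed → moving: a material point at
exhale position `p` moves to `p + u(p)` at inhale. `V_jac > −1` wherever
the deformation is invertible; positive values mark inspiratory expansion.
Percentile normalization converts the map to ranks over the lung mask
(average ranks for ties, scaled to (0, 100]); the top-p% functional ROI is
the set of lung voxels whose percentile strictly exceeds `100 − p`, which
for distinct values contains exactly ⌊p%·N⌋ voxels and guarantees nesting
across thresholds. Percentiles are computed jointly over both lungs;
negative-`V_jac` voxels are retained (they carry rank information).

Registration is deliberately pluggable: any displacement field on the
fixed grid can be supplied. The built-in method is SimpleITK's
multi-resolution B-spline registration with a mean-squares metric on the
full voxel set and an LBFGS-B optimizer — fully deterministic (no
stochastic sampling). Default control-point spacing is 30 mm with a
(4, 2) shrink pyramid; on smooth phantom fields of 2–5 mm displacement
this recovers the ground truth with mean endpoint error well below one
in-plane voxel inside the lung. No claim is made that it reproduces any
specific clinical registration package; the downstream science depends
only on the field.

## Synthetic thorax phantom

The phantom exists so that every downstream quantity has an exact oracle.

* **Deformation.** `u(x) = (a₀ + g·(x−c))(x−c) + Σₖ Aₖ exp(−rₖ²/2σₖ²)(x−pₖ)`:
  a spatially graded expansion about the thorax center `c` (base
  coefficient `a₀ = 0.05`, gradient `g` of order 10⁻⁴/mm giving the
  dominant ventilation gradient seen in real maps) plus radial Gaussian
  "breathing units" (`A` ≈ ±0.03…0.10, σ ≈ 20–30 mm) for localized hyper-
  or hypo-ventilation; a negative-amplitude unit at the tumor models the
  ventilation defect of an airway-obstructing mass. The displacement
  gradient, hence `det(I+∇u) − 1`, is available analytically; generation
  rejects patterns whose minimum determinant drops below 0.05
  (near-singular deformation).
* **Images.** Two-compartment intensities (lung −800 HU, soft tissue
  +40 HU) with a smooth analytic sinusoidal texture (amplitude 60 HU)
  inside the lung so registration has interior signal, plus one shared
  Gaussian noise realization (σ = 10 HU; shared, so a zero deformation
  maps exhale onto inhale voxelwise). The inhale image is the pushforward
  of the analytic exhale anatomy through the deformation, sampled by
  fixed-point inversion of `x + u(x)` at every voxel — no grid
  interpolation enters the ground truth. CT realism is a non-goal; the
  phantom needs contrast and exact geometry, not texture fidelity.
* **Grid.** Default 96×72×40 voxels at (0.8, 0.8, 5.0) mm — the pixel and
  slice spacing of routine thoracic 4DCT protocols on a miniature thorax
  (two ellipsoidal lungs with 13/16/70 mm semi-axes). The miniature extent
  keeps a full 17-patient, 6-strategy study to tens of seconds while
  preserving the anisotropy that margin expansion, gradients and Hausdorff
  distances must respect.
* **Structures.** IGTV = tumor sphere; CTV = IGTV + 5 mm; PTV = CTV +
  5 mm (Euclidean margins in mm, anisotropy-aware). Heart, esophagus and
  spinal cord are simple ellipsoid/cylinder stand-ins for OAR reporting.
* **Dose.** Plans are emulated, not optimized: `1.05 × 60 Gy` inside the
  PTV with a logistic falloff in distance-to-PTV (scale 12 mm, steepness
  scale/4) and σ = 0.3 Gy noise, which keeps PTV V60 ≥ 95 % by
  construction. A functional strategy multiplies dose by
  `avoidance_factor` (default 0.5) inside its ROI minus the PTV. No
  dose is redistributed elsewhere; consequently every avoidance strategy
  can only lower lung metrics, whereas a real optimizer trades dose and
  can raise fV10 for narrow (top10/20) avoidance. The package's
  qualitative claims therefore concern the top30–top50 direction, which
  the emulation does reproduce.
* **Cohorts.** The benefit scenario draws large tumors (9–12 mm radius)
  with the expansion gradient toward the tumor and a hyper-ventilating
  unit abutting the PTV; the non-benefit scenario draws small distant
  tumors (4–6 mm) with the gradient away, the unit in the opposite lung
  and a broad peritumoral defect — mirroring the clinical finding that
  tumor size and the distance between PTV and high-function lung separate
  the groups. Default study arms are 8 benefit and 9 non-benefit
  patients. All randomness flows through `numpy.random.SeedSequence`
  spawning, so cohorts are bit-reproducible under a fixed seed.

What passing tests on this phantom do **not** show: performance on real
CT texture, sliding-motion discontinuities at the pleura, registration
error on noisy clinical 4DCT, or optimizer behaviour under competing
constraints.

## Dosimetry conventions

* `Vx` uses the inclusive threshold `D ≥ x Gy` so `V0 = 100 %` holds
  identically (measure-zero difference on continuous dose).
* DFH weights default to the percentile ventilation value (maps are
  percentile-normalized before planning); `raw_positive` weighting
  (`max(V_jac, 0)`) is selectable, and the choice is recorded in output
  metadata because published studies rarely state it.
* The lung evaluation domain defaults to total lung minus IGTV
  (`lung_minus_ptv` and `whole_lung` selectable).
* HI is ICRU-83 `(D2% − D98%)/D50%`; CI defaults to Paddick
  `TV_PIV²/(TV·PIV)` with the RTOG ratio `PIV/TV` as a variant. Scalar
  metrics are computed exactly from voxel values; the exported cumulative
  curves use 0.1 Gy bins over 0–80 Gy.
* Hausdorff distances are classic maximum HD between surface-voxel-center
  sets (face-connectivity surface extraction); an HD95 variant is
  available. Margins and distances are Euclidean in mm.

## NTCP and benefit rule

`NTCP = Φ((fV10 − TD50)/(m·TD50))` with m = 0.53 and TD50 = 54.1 (fV10 on
the 0–100 % scale — the TD50 value is only meaningful there). The probit
(Lyman-type) functional form is a documented choice; a slope-matched
logistic alternative sits behind a config flag. A patient is classified
into the benefit group iff the minimum NTCP over the functional
strategies is strictly below the anatomical value (ties → non-benefit);
the comparison set is configurable because cohort reports rarely state
which single functional plan defined their grouping.

## Statistics

Paired strategy comparisons gate on Shapiro–Wilk normality of the paired
differences at α = 0.05: normal → two-tailed paired t-test, otherwise
two-tailed Wilcoxon signed-rank (the statistically appropriate paired rank
test; a literal rank-sum is available by flag for parity with reports
that quote one in a paired setting). Group comparisons apply the same
gate per group (t-test vs rank-sum). All-zero differences short-circuit
to a degenerate result with p = 1. Significance is marked at p < 0.05 and
p < 0.01 per comparison with no multiple-testing correction, matching the
per-comparison reporting convention of planning studies. Summary tables
report mean ± SD per (group, strategy, metric); NTCP rows are means of
per-patient NTCP values.

## Numerical notes and limitations

* Finite-difference ventilation is exact for affine fields and O(h²) on
  smooth fields; the 5 mm slice spacing dominates the error (~2×10⁻³ on
  default phantoms). The test suite verifies the ~4× error drop under
  voxel-size halving.
* Fixed-point inversion of the deformation converges geometrically for
  the gradient bounds the phantom enforces; 30 iterations leave residuals
  far below interpolation error.
* NIfTI affines are stored in 32-bit floats: voxel data round-trips
  bit-exactly, spacing/origin to ~10⁻⁷ relative. Rotated/sheared affines
  are rejected rather than silently resampled.
* Problem sizes: default studies use the miniature 96×72×40 grid;
  registration tests use a 48×36×32 near-isotropic grid. These are the
  package's chosen desk-scale study conditions, stated here once;
  acceptance and test results quote them via `n`.
* Published cohort values bundled in `ctvent.reference` are fixed inputs
  for arithmetic cross-checks and example fixtures; the package does not
  (and cannot, absent the images) re-derive them.
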