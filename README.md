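# ctvent

Analysis toolkit for **CT-ventilation-guided functional lung avoidance
radiotherapy**. It is written for medical-physics and image-analysis
researchers who want to study — quantitatively and reproducibly — when
steering dose away from highly-ventilated lung actually lowers the risk of
radiation pneumonitis (RP), and for whom.

## The science in brief

Respiration-correlated CT (4DCT) lets regional lung function be estimated
without extra imaging: deformably registering the peak-exhale volume to the
peak-inhale volume yields a displacement field `u(x)`, and the local volume
change on inspiration

```
V_jac(x) = det(I + ∇u(x)) − 1
```

serves as a per-voxel ventilation surrogate (positive = expansion =
ventilated tissue). The map is rank-normalized to a percentile image over
the lung, and the top 10–50 % percentile regions define functional-lung
avoidance structures for planning.

Given one dose grid per planning strategy (an anatomical plan plus
functional plans sparing top10 … top50), the toolkit evaluates:

* **DVH metrics** over the lung: `Vx` (% of lung volume ≥ x Gy), `MLD`;
* **DFH metrics**, the ventilation-weighted analogues: `fVx` (% of total
  lung *function* ≥ x Gy), `fMLD`;
* **PTV indices** (ICRU-83 homogeneity, Paddick conformity, V60 coverage)
  and OAR statistics (heart Dmean/V45, esophagus Dmean, cord Dmax);
* **NTCP** for grade 2+ RP from fV10 with the probit model
  `NTCP = Φ((fV10 − TD50)/(m·TD50))`, m = 0.53, TD50 = 54.1;
* **benefit classification** (a patient benefits iff some functional plan
  has strictly lower NTCP than the anatomical plan), Hausdorff distances
  between PTV and functional lung, and normality-gated paired/group
  statistics for cohort tables.

Because no public 4DCT + plan dataset exists at desk scale, the package
ships a first-class **synthetic thorax phantom**: an analytic breathing
deformation (graded expansion + Gaussian breathing units) whose Jacobian —
and therefore the ground-truth ventilation of every voxel — is known in
closed form, plus emulated per-strategy dose grids. Every downstream
number can be checked against an exact oracle.

## Worked example

```python
from ctvent import (PhantomSpec, generate_patient, jacobian_ventilation,
                    percentile_normalize, functional_rois)
from ctvent.phantom import GaussianBump, VentilationPattern

spec = PhantomSpec(
    ventilation_pattern=VentilationPattern(
        base_expansion=0.05, expansion_gradient=(0.0, 0.0, 3e-4),
        bumps=(GaussianBump((-18.0, 0.0, 30.0), 0.08, 25.0),)),
    seed=42)
patient = generate_patient(spec)
vmap = percentile_normalize(
    jacobian_ventilation(patient.true_field, patient.masks["lungs"]))
rois = functional_rois(vmap)
```

Running `python examples/01_ventilation_map.py` (which does exactly this)
prints:

```
lung volume: 122.2 cm^3 (38176 voxels)
V_jac over lung: mean 0.2033, range [0.0699, 0.4885]
max |finite-difference - closed-form| (interior): 2.11e-03
top10: 3818 voxels = 10.00% of lung
...
top50: 19088 voxels = 50.00% of lung
```

The mean V_jac of 0.20 says the phantom lung expands ~20 % on inspiration;
the `2.11e-03` line is the finite-difference error against the closed-form
Jacobian (bounded by the 5 mm slice spacing squared); and each top-p% ROI
holds exactly p% of lung voxels because the map is rank-normalized.

`examples/03_ntcp_benefit.py` continues to dose and risk for one patient:

```
strategy      fV10 %  NTCP %
anatomical     51.43   46.29
top30          47.20   40.49
top50          45.75   38.54
group: benefit (lowest-risk functional plan: top50)
```

— sparing the top-50 % ventilated lung cuts this patient's predicted RP
risk by ~8 percentage points, so the patient is classified into the
benefit group. `examples/04_cohort_study.py` runs the two-arm cohort
version with significance tests.

A thin CLI mirrors the library for shell use:

```
ctvent run-all out/ --n 4 --scenario mixed --seed 1
ctvent simulate cohort/ --n 2 --seed 7
```

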