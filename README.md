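# lvforce

Global left-ventricular (LV) hemodynamic force from time-resolved,
three-directional (4D flow) velocity fields.

During diastolic filling the LV myocardium decelerates the inflowing blood;
by action–reaction the blood pushes back on the wall.  In healthy ventricles
this global force stays aligned with the base–apex axis; in dilated,
dysfunctional ventricles it tips sideways.  `lvforce` quantifies this from
velocity data alone: it computes the intraventricular pressure-gradient field
from the Navier–Stokes momentum balance for an incompressible Newtonian fluid
(body forces excluded),

    ∇p = −ρ ∂v/∂t − ρ (v·∇)v + μ ∇²v ,

with ρ = 1060 kg/m³ and μ = 0.004 N·s/m², and integrates it over the
segmented LV cavity at every cardiac frame:

    F(t) = ∫_LV ∇p dV        (= ∮ p n̂ dS, the pressure force of the blood
                               on its surroundings).

F(t) is projected onto an anatomical frame (base→apex long axis `e_long`,
anteroseptal→inferolateral in-plane axis `e_sax1`, and `e_sax2` completing
the triad), the cycle is divided into systole / E-wave / diastasis / A-wave
from speed traces at the mitral-valve and LV-outflow landmarks, and each
filling wave is summarized by

* the **SAx-max/LAx-max force ratio** `max|F_sax1| / max|F_long|` within the
  wave window (≈0.2 in healthy LVs, higher when the force is less
  apex-directed), and
* the **time-averaged SAx-plane force** `mean √(F_sax1² + F_sax2²)` (N).

The package is aimed at cardiovascular MR physicists and image-analysis
researchers who have 4D flow velocity reconstructions plus an LV
segmentation and want reproducible force traces, per-subject metrics and
group statistics.  Because no public 4D flow datasets accompany the original
clinical studies of this quantity, `lvforce` ships a first-class synthetic
phantom module: analytic validation fields with closed-form forces, and a
physiologic LV phantom with prescribed force programs, biphasic inflow,
acquisition noise, polynomial background offsets and velocity aliasing,
plus cohort presets calibrated to published healthy / dilated-cardiomyopathy
(DCM) group statistics.

## What's inside

| module | role |
| --- | --- |
| `lvforce.io` | NIfTI + JSON-sidecar readers/writers, mask resampling onto the velocity grid/time base |
| `lvforce.preprocess` | temporal phase-unwrap (VENC aliasing), degree-4 polynomial background correction with a static-tissue soft mask |
| `lvforce.hemodynamics` | masked Navier–Stokes pressure gradients and the force integral |
| `lvforce.geometry` | anatomical axes, force projection, speed traces, cardiac-phase detection |
| `lvforce.metrics` | per-subject ratios, mean transverse force, loop orientation, velocity→force peak lag |
| `lvforce.phantom` / `lvforce.presets` | analytic and LV phantoms, artifact injection, cohort generation |
| `lvforce.stats` / `lvforce.pipeline` | unpaired t-tests, ratio~sphericity regression, end-to-end subject/cohort runs |
| `lvforce.cli` | `lvforce compute / phantom / cohort-gen / cohort` |

## Worked example

Build one synthetic healthy subject with a prescribed force program and run
the full pipeline on its noisy, aliased, offset-corrupted field:

```python
from lvforce import PhantomSpec, lv_phantom, analyze_subject, PipelineConfig

spec = PhantomSpec(edv_ml=137, ef=0.61, si=0.56, ratio_e=0.23, ratio_a=0.26,
                   mean_sax_e=0.032, mean_sax_a=0.034, seed=7)
subject = lv_phantom(spec)
m = analyze_subject(subject.field, subject.seg, subject.landmarks,
                    covariates={"si": spec.si}, config=PipelineConfig())
```

prints (via the obvious format strings):

```
ratio_e    = 0.226   (prescribed 0.230)
ratio_a    = 0.264   (prescribed 0.260)
mean_sax_e = 0.0348 N (prescribed 0.0320)
mean_sax_a = 0.0314 N (prescribed 0.0340)
edv        = 137.0 mL   peak_lag_e = 100 ms   loop_e = CW
```

The prescribed E-wave ratio 0.23 is recovered as 0.226 after the pipeline
has undone the injected aliasing and background offsets; the residual
differences come from the injected velocity noise (0.02 m/s per component)
jittering the detected wave windows by about a frame.  `edv` is read back
from the resampled mask, and `peak_lag_e` is the delay from the transmitral
speed peak to the force peak during early filling.

From the shell the same subject-level run is
`lvforce compute --subject sub-01/ --out results/`, which writes
`force_trace.csv` (frame, time, Fx/Fy/Fz, F_long/F_sax1/F_sax2, phase label)
and `metrics.csv`.  Cohorts: `lvforce cohort-gen --preset dcm --n 10 --seed 1
--out dcm/` and `lvforce cohort --group-a healthy/ --group-b dcm/ --out report/`.

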