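# Methods

This note documents the model, the numerical choices and the synthetic-data
design behind `lvforce`, including the places where the design was genuinely
open and what the package chose.

## Physical model

Blood is treated as an incompressible Newtonian fluid (ρ = 1060 kg/m³,
μ = 0.004 N·s/m²; both configurable on `AcquisitionMeta`).  With body forces
excluded, the momentum balance gives the pressure gradient at every voxel of
the segmented LV cavity,

    ∇p = −ρ ∂v/∂t − ρ (v·∇)v + μ ∇²v   [Pa/m],

and the global hemodynamic force is the volume integral of ∇p over the
instantaneous LV mask.  The sign convention is fixed by the divergence
theorem: `F = +∫ ∇p dV = ∮ p n̂ dS` with outward normal, i.e. the pressure
force the intracavitary blood exerts on its surroundings.  All direction
language downstream ("toward apex" = positive `F_long` with `e_long`
pointing base→apex) refers to this convention.

Assumptions and knowingly accepted simplifications:

* **Eulerian terms over a moving mask.**  The integral is taken over the
  instantaneous mask; no wall-motion (moving-boundary material-derivative)
  correction is applied.  Border-voxel contributions are a small fraction of
  the integral; an optional one-voxel mask erosion (`PipelineConfig.erode`)
  exposes the sensitivity.
* **Viscous term retained but minor.**  At 3 mm voxels the Laplacian of a
  measured velocity field is underresolved in the wall shear layer; the term
  is included by default (`include_viscous`) and is orders of magnitude below
  the transient term in all phantom regimes.
* **No turbulence or non-Newtonian rheology.**

## Discretization

* Spatial derivatives: second-order central differences using only in-mask
  neighbours, degrading to one-sided first differences (and one-sided
  3-point second differences) at the mask boundary.
* Validity is tracked **per term**: a voxel that lacks a usable viscous
  stencil still contributes its transient and convective parts.  Each term
  is integrated over its own valid set; zero-filling unavailable stencils
  instead would bias the surface contribution, which dominates the integral,
  and excluding a voxel for *all* terms when only the Laplacian is
  unavailable measurably biases the transient integral on coarse grids.
* Temporal derivative: cyclic central difference over the cardiac cycle
  (retrospective gating makes frame N−1 precede frame 0), gated by the
  stencil frames' masks with a one-sided fallback where the voxel leaves the
  mask.  Non-uniform frame times are supported; the default is uniform
  `rr_interval / n_frames`.
* Verified convergence: on the uniformly oscillating ball the force error is
  second order in Δt (exactly the `sin(ωΔt)/(ωΔt)` factor of the cyclic
  central difference) and second order overall under combined grid/frame
  refinement; the steady Poiseuille profile reproduces
  `∇p_z = −4μV/R²` to machine precision because second differences of a
  quadratic are exact.

## Preprocessing

* **Phase unwrap** (aliasing beyond ±VENC): temporal, cyclic, starting from
  the frame of minimal global mean speed; each voxel/component series is
  shifted frame by frame by the multiple of 2·VENC in {−2…2} that minimizes
  the jump from its unwrapped predecessor.  Valid when true magnitudes stay
  below 5·VENC and cyclic frame-to-frame jumps stay below VENC; the phantom
  enforces exactly this envelope.  An exhaustive minimum-total-variation
  search over wrap integers serves as the test oracle.
* **Background (eddy-current) offsets**: modelled as time-constant, fit per
  component as a polynomial of total degree ≤ 4 (35 terms) in physical
  coordinates to the time-averaged velocity by weighted least squares.  The
  weight per voxel is `exp(−(SD_t(speed)/s)²)` with s = 0.05 m/s
  (`sd_scale`): the published corrections this emulates use a "weighted soft
  mask" whose exact rule is not public, so this Gaussian-in-temporal-SD
  weight is this package's own stand-in.  Coordinates are rescaled to
  [−1, 1] for conditioning.  Order of operations: unwrap first (wraps
  corrupt the temporal mean the fit uses), then background removal.

## Geometry and phases

* `e_long = normalize(apex − mv_center)`; the three-chamber plane is spanned
  by `e_long` and the MV→AoV direction orthogonalized against it; `e_sax1`
  is that in-plane direction signed to point away from the aortic
  (anteroseptal) side, overridable by an explicit `rv_direction`;
  `e_sax2 = e_long × e_sax1`.  The "basal short-axis plane" is the fixed
  (`e_sax1`, `e_sax2`) coordinate plane — the force is one global vector, so
  only the plane's orientation matters, and a per-frame anatomical slice
  would add nothing.
* The reference origin is the mask center of mass at the first E-wave frame
  ("a time in early diastole"); it does not enter any metric, since forces
  are free vectors.
* Phase detection uses speed traces trilinearly interpolated at the MV and
  AoV landmarks, lightly smoothed (3-frame cyclic moving average).  Systolic
  outflow is located from the AoV peak and its fall below `onset_frac`
  (default 0.05) of that peak.  The E-wave is the **first** prominent
  diastolic wave — the first local maximum reaching ≥ 40% of the diastolic
  peak — not the global maximum, because the atrial wave can exceed the
  early wave when relaxation is impaired.  Wave onsets are the first frame
  above `onset_frac` of the wave peak, walked back to the nearest local
  minimum; wave ends are where the deceleration ends; the A-wave ends at
  end-diastole.  Everything before the E-wave onset (ejection plus the
  isovolumic intervals) is labelled systole, so the four windows always
  partition the cycle.  Detection is invariant to uniform scaling of the
  traces.  A missing second wave yields an empty A-wave with a warning
  (fused inflow); flat traces are an error.

## Metrics

* `ratio_w = max|F_sax1| / max|F_long|` over the frames of wave
  w ∈ {E, A}; maxima of the absolute signed projections within the wave
  window (per-wave extrema, direction-agnostic, invariant to positive
  rescaling of the trace).  Note the transverse component is in the
  numerator: the ratio grows when the force is less apex-aligned.
* `mean_sax_w = mean √(F_sax1² + F_sax2²)` over the wave's frames.
* Loop orientation: sign of the shoelace area of the (F_long, F_sax1)
  trajectory; |area| < 1e−6 N² is reported indeterminate.
* `peak_lag_e`: time of max |F| minus time of max MV speed within the
  E-window (positive = force later).
* `edv`: maximum mask volume over the cycle — the mask is the only geometry
  the pipeline holds.  The sphericity index enters as an externally supplied
  scalar covariate.

## The LV phantom

The phantom emulates a retrospectively gated 4D flow acquisition of a
contracting/relaxing LV on a 40×40×56 grid of 3 mm voxels, 40 frames over a
1000 ms cycle, VENC 1.0 m/s (the clinical regime the method targets).

* **Geometry**: a prolate ellipsoidal cavity whose aspect is set by the
  subject's sphericity index (SI = diameter/length) and whose volume follows
  a waveform with EDV plateaus at the cycle ends, cosine systolic emptying
  to ESV = EDV·(1−EF), an E-wave refill of 70% of the stroke volume, flat
  diastasis, and an A-wave refill of the rest.  Per-frame masks are obtained
  by order statistics of the ellipsoidal radius field, which makes the
  voxelized volume match the waveform to half a voxel (and the pipeline-read
  EDV match the prescription to better than two voxel volumes).  The
  segmentation is emitted on its own base — 30 frames, 2× finer in-plane
  grid — so every run exercises the nearest-neighbour spatial/temporal mask
  resampling exactly as with real morphology stacks.
* **Jets**: compact transmitral (E/A lobes) and LV-outflow (systolic lobe)
  jets centred at the MV/AoV landmarks give the landmark speed traces their
  clinical shape (healthy E jet 0.8 m/s, A 0.5, outflow 1.1; reduced inflow
  and outflow speeds for the DCM presets).  The outflow jet deliberately
  exceeds VENC so every cohort run exercises aliasing correction.
* **Force program**: per wave and per anatomical axis the bulk velocity
  carries a smooth momentum bump (sin² in normalized time, slightly skewed
  per axis so the projected trajectories trace open loops); since the force
  integral is, to leading order, −ρ d/dt of the in-cavity momentum, each
  bump produces a force lobe confined to its wave window.  The bulk field is
  the bump momentum divided by the instantaneous apodized volume, times a
  flat-cored boundary apodization (cos² in the cubed normalized radius).
* **Calibration by construction**: bump amplitudes are not set open-loop.
  The generator runs its own pressure-gradient pipeline twice on the
  noiseless field (jets only, then jets + reference bulk), detects the wave
  windows from the noiseless traces, and solves the resulting affine
  trace models so that the measured `mean_sax` and ratio equal the
  prescribed targets exactly on the noiseless field.  This absorbs every
  discretization effect (stencils, mask motion, jet momentum flux) into the
  construction; the remaining pipeline-vs-prescription error on noisy data
  comes from the injected noise only.
* **Weak compressibility, deliberately.**  A compactly supported,
  exactly divergence-free field with no boundary flux has zero net momentum
  (apply the divergence theorem to `x_i v_j`), so a solenoidal no-flux
  phantom could carry no global force at all.  The bulk field is therefore
  smooth but weakly compressible — as measured phase-contrast data
  effectively are — and no divergence projection is applied.
* **Ground-truth cross-check**: for jet-free phantoms the momentum oracle
  `−ρ d/dt ∫ v dV` is an independent route to F and agrees with the
  pressure-gradient integral to a few percent; with jets enabled the
  transvalvular momentum flux makes the oracle long-axis component only
  approximate, which is why the dual-route test runs on the jet-free
  configuration.
* **Force cap**: the programmed per-wave long-axis peak is capped at 1.5 N;
  a near-zero prescribed ratio with a finite transverse force would
  otherwise demand unbounded long-axis force and unphysical bulk speeds.
  Capped subjects are rare tail draws and shift a cohort mean by ≪ one
  standard error.
* **Artifacts**: per-component Gaussian noise of 0.02 m/s (mid-range for
  clinical 4D flow at VENC 1 m/s), a random smooth polynomial offset field
  of ~1 cm/s scale (degree ≤ 2 when sampled; the corrector fits degree 4),
  then aliasing into [−VENC, VENC).

* **Cohort presets** (`lvforce/presets.py`) parameterize per-subject draws
  of the force ratios, mean transverse forces, EDV, EF and SI from published
  healthy and DCM group statistics (means ± SD), with positive truncation
  and a within-group SI↔ratio coupling of 0.3.  They are simulation inputs,
  not re-derivations.  Cohort generation is a pure function of
  (preset, n, seed).

## What the phantom does and does not show

Passing the recovery tests shows the pipeline chain — artifact correction,
resampling, masked Navier–Stokes evaluation, integration, projection, phase
detection, metrics — is internally consistent, unbiased at realistic noise,
and correct against closed forms.  The phantom's flow is *not* CFD-grade:
no vortices, no valve geometry, a programmed rather than emergent force,
and weak compressibility.  Recovery on phantoms therefore validates the
measurement chain, not the clinical physiology of real intraventricular
flow.

## Statistics

Unpaired two-sided t-tests compare groups; the default variant is the
pooled-variance Student test (the convention of the clinical literature this
mirrors), Welch available by flag, and both accept summary-statistic input
(mean, SD, n).  The ratio~SI relation is ordinary least squares pooled over
both groups (n = 20): the relation is tested across the disease spectrum,
and the group separations themselves carry most of the pooled variance.  No
multiple-testing correction is applied (four primary comparisons, α = 0.05,
reported as-is).  Type-I calibration of the cohort comparison is verified by
simulation (same-preset groups, 500 seeded replicates at n = 5 per group).

## Problem sizes

Default phantom grids (40×40×56 × 40 frames) and cohort sizes (10/10/5)
match the emulated acquisitions; the analytic oracles run at 64³.  Unit
tests use 32×32×44 phantoms; all sizes are package choices exposed through
`PhantomSpec`.
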