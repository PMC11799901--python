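# Methods

`sctqa` re-creates, on fully synthetic data, the analysis a medical-physics
team runs when deciding whether a synthetic CT (sCT) produced in an MR-only
brain radiotherapy workflow can be trusted for an individual patient:
recompute the plan dose on each candidate image set with monitor units
unchanged, quantify the dose differences, apply tolerance limits, and check
the impact on kV-image-based patient positioning. This note documents the
models, the defaults, and the reasoning behind the open design choices.

## The synthetic head phantom and its error modes

Clinical MR-only cohorts are private, so every stage is exercised on a
parametric digital head: an ellipsoidal body (default semiaxes 70/85/80 mm)
with a skull shell (800 HU, 6 mm), brain tissue (30 HU), an air sinus box,
and a spherical PTV (12 mm radius) placed either near the sinus or deep in
the brain. The default grid is 96^3 voxels at 2 mm — the slice thickness of
a typical planning CT — which keeps a full dose + gamma evaluation of one
patient in the seconds range.

The HU values are chosen so the clinical thresholding convention (brain =
[-100, 100] HU, skull >= 100 HU, inside the body) recovers the planted
compartments *exactly* on the noise-free CT; this is asserted by tests. A
voxel at exactly 100 HU belongs to both windows — a deliberate, documented
quirk of the interval definitions as used in practice.

The skull additionally carries deterministic bony landmarks (a septum plate
inside the sinus, a skull-base plate with a foramen, two asymmetric
mastoid-like studs). These exist because bone-driven 2D/2D registration of
a *smooth* ellipsoidal shell is nearly degenerate in rotation: projections
change by well under 1% NCC per degree, and pose recovery stalls at a few
tenths of a degree. Real skulls are full of such landmarks; the phantom
needs just enough of them to anchor all three rotation axes.

The paired sCT is the same anatomy pushed through one error mode:

| mode | emulates | parameters (defaults) |
|---|---|---|
| `NONE` | a faithful AI generator | Gaussian HU noise only (sigma 20 HU, body only) |
| `SYSTEMATIC_BIAS` | a soft-tissue density bias | constant HU shift in the brain window |
| `SINUS_MISPREDICTION` | sinus-region prediction failure | air cavity filled with 30 HU tissue |
| `METAL_ARTIFACT` | an implant corrupting the MR/sCT | 3000 HU sphere (8 mm) + radial streaks (±300 HU) lateral to the PTV, on a beam path |
| `BULK_DENSITY` | bulk-density class assignment | HU quantised to {-1000, 0, 700} at thresholds -200/150 HU |

Noise is applied to the sCT only; the CT is the ground truth. Per-patient
seeds derive deterministically from the cohort master seed and patient id
and are recorded in the truth table. Only `METAL_ARTIFACT` is labelled a
planted *failure*: the other modes produce dose signatures at or below the
1% tolerance scale by construction.

`calibrate_bias` bisects the soft-tissue HU shift (plain or as the
bulk-density soft-class offset) until the mean PTV dose error against the
CT hits a target (default -1%, the classic signature of a bulk-density
generator). Denser soft tissue attenuates more, so the dose error is
monotone decreasing in the shift and the bisection is well posed; the
bracket is ±300 HU and the stopping width 0.05 percentage points.

What the phantom does *not* model: anatomical variability between patients
(only seeds and planted modes vary), MR acquisition physics, couch and mask
hardware, CT noise, and realistic artifact textures. Passing tests
demonstrate that the *analysis machinery* behaves correctly and detects the
planted signatures — not that any particular clinical generator would pass
or fail.

## The toy dose engine

The engine exists so that two images produce two comparable dose grids; it
is primary-photon attenuation only, an explicit departure from clinical
algorithms (no scatter, no electron transport, no heterogeneity kernels):

    D(v) = MU * sum_b w_b * exp(-mu_eff * WEPL_b(v)) * L_b(v) * (SAD / |v - s_b|)^2

* `WEPL_b(v)`: water-equivalent path length from the beam source to the
  voxel, by exact Siddon voxel-boundary traversal of the density grid.
  HU map to relative density through a piecewise-linear calibration,
  clamped at the ends and pinned at (0 HU, 1.0).
* `L_b`: 1 inside the circular aperture (projected to the isocenter
  plane), Gaussian rolloff (sigma 3 mm) beyond it.
* `mu_eff = 0.005/mm`, a textbook effective megavoltage attenuation scale.
* Default plan: 4 coplanar beams at 0/90/180/270 deg, SAD 1000 mm,
  aperture = PTV radius + 5 mm, prescription 60 Gy.

`MU` ("monitor units") is fixed by normalising the mean raw PTV dose on the
*reference CT* to the prescription, and is then reused verbatim for every
sCT recalculation — the monitor-units-unchanged contract that makes HU
errors visible as dose errors. Dose is computed on the image grid itself;
beam contributions below a lateral factor of 1e-6 are treated as zero.

## Metrics

* **Mean error**: mean signed voxel dose difference (evaluated minus
  reference) inside a structure, in Gy and in % of prescription. Both
  grids must coincide (resample first).
* **DVH metrics**: D2%, D95%, D98%, Dmean. Convention: voxel doses sorted
  descending, voxel k of N carries cumulative volume fraction k/N, linear
  interpolation between those nodes, x below 100/N returns the maximum.
  Deltas are (evaluated - reference)/prescription in %.
* **3D local gamma** (default 1%/1 mm, 20% low-dose threshold, cap 2):
  for each reference voxel above threshold, the minimum over a spherical
  offset lattice (step = distance_mm/10) of
  sqrt(d^2/Delta^2 + dD^2/(delta% * D_ref)^2), with the evaluated dose
  trilinearly interpolated. The production search visits offsets in order
  of increasing distance and retires a voxel once its running minimum
  beats every remaining purely-spatial term — an exact pruning, verified
  voxel-for-voxel against the exhaustive `gamma_bruteforce` oracle.
  Voxels that never beat the cap count as failures. The threshold governs
  both inclusion and the local denominator, so the denominator can never
  be pathologically small.

The reference/evaluated direction follows the QA framing: the comparison
image set (CT or a QA generator's sCT) is the reference; the clinical sCT's
dose is evaluated.

## Classification

Point metrics accept iff |value| <= 1% (inclusive); gamma accepts iff the
pass rate >= 90% (inclusive). "Positive" means *the sCT is accepted*; a QA
generator's verdicts are scored against the CT verdicts as TP/FN/FP/TN, and
sensitivity = TP/(TP+FN). Specificity is reported as well but comes back
missing when no condition-negatives exist (the usual situation — genuine
sCT failures are rare). Patients a generator refuses (artifact
auto-rejection) are excluded from that generator's counts and logged.

## Positioning

kV acquisition is simulated by resampling the bone-weighted attenuation
field (HU < 150 suppressed) under a rigid pose and projecting two
orthogonal views with the same Siddon tracer (virtual detectors through the
isocenter, 112^2 pixels at 2 mm, SAD 1000 mm), plus multiplicative Gaussian
noise (1%). Registration recovers the 6-parameter pose by maximising mean
NCC over the two views in three stages: FFT cross-correlation initialises
the translations; a 1-degree lattice over ±5 degrees (reduced detector
resolution) initialises the rotations and raises a `multi_optimum` flag
when a second optimum sits within 1% similarity but more than 2 degrees
away; Nelder-Mead then refines all six parameters using *exactly* the
acquisition forward model (resample attenuation, project), first on a
2x-subsampled detector, then at full resolution, restarting once from the
strongest well-separated rotation rival. Sharing the forward model between
simulation and refinement is what makes the objective peak at the true pose;
approximating the posed projection by inverse-transformed rays (as the
coarse stage does for speed) biases flat rotation axes by a few tenths of a
degree.

A full 6-parameter coarse grid at the nominal lattice would take ~12M
projections and is not tractable; the staged search above reaches
millidegree-scale recovery in ~15 s per registration on one core.

The QA quantity is the per-axis difference between the CT-based and
sCT-based couch corrections, minus the static sCT/CT registration offset
(from a coarse-to-fine 3D NCC registration), composed additively per axis —
a small-angle approximation whose error is below 0.01 degrees for rotations
up to 5 degrees. Pose convention: translations (lateral, longitudinal,
vertical) applied after intrinsic x→y→z rotations about the isocenter.

## Study orchestration

`run_study` simulates the cohort, computes CT and clinical-sCT doses per
patient, emulates each QA generator (faithful + artifact auto-reject;
faithful + sinus misprediction on near-sinus patients; calibrated
bulk-density), evaluates all metrics per reference, applies tolerances,
builds the sensitivity matrix, summarises each metric distribution as a
boxplot record (type-7 linear-interpolation quartiles, 1.5 IQR fences,
outliers tagged with patient ids), and attaches Wilcoxon signed-rank
p-values (delegated to scipy) for each generator-vs-CT distribution.
Everything is deterministic per master seed and written with stable
formatting, so identical runs are byte-identical.

## Numerical choices and degenerate inputs

* Siddon traversal is exact for piecewise-constant density; ties at voxel
  corners advance all crossing axes at once. Zero-length or grid-missing
  segments return 0.
* Gamma excludes evaluated samples outside the evaluated grid's support;
  a reference voxel with no valid sample reports the cap. An all-zero
  reference dose is rejected (threshold undefined).
* DVHs reject empty structures; `dose_at_volume` rejects x outside
  (0, 100].
* Resampling fills out-of-support voxels with -1000 HU (air) for images
  and 0 for dose/attenuation; masks use nearest-neighbour.
* The registration similarity floor is NCC 0.2 (status "failed" below).
* Problem sizes used by the test suite and acceptance script (96^3 cohort
  of 20, 5-10 registration seeds, 16^3-32^3 gamma oracle grids) are chosen
  to keep a full run in the tens of minutes on a single core.

## Known limitations

* The dose model's absolute dose distributions are not clinically
  meaningful; only *differences* between recalculations are.
* One phantom anatomy underlies the whole cohort; cohort variability is
  noise + planted modes, so sensitivity values describe the machinery, not
  any clinical generator population.
* The gamma implementation is validated against its own exhaustive oracle
  and closed forms; no third-party gamma library is available in this
  environment for an external cross-check.
* 2D/2D registration assumes the kV chain's geometry is known exactly;
  detector calibration errors are out of scope.
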