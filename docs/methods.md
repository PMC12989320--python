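# Methods

This note documents the models, conventions and numerical choices behind
`unidose`, in the spirit of a package methods appendix: what is computed, why
the defaults are what they are, and what the synthetic experiments do and do
not demonstrate.

## Grid and geometry conventions

All volumes in a case (masks, channels, doses) share one isotropic grid.
Voxel indices are 0-based; world coordinates are millimetres; the centre of
voxel `(i, j, k)` is `origin + index * spacing`. The canonical spacing is
2 mm isotropic; `read_volume(..., resample_to_mm=2)` resamples arbitrary
inputs (masks with nearest-neighbour so they stay binary, doses/channels
trilinearly). The in-plane extent is whatever the generated or loaded grid
provides; production-scale grids only change `grid_shape`.

Beams are coplanar and rotate about the z (superior–inferior) axis: for
gantry angle θ the source sits at `iso + SAD·(sin θ, cos θ, 0)` with
SAD = 1000 mm (standard linac value; configurable). The beam's-eye-view
(BEV) plane passes through the isocenter perpendicular to the central axis;
projection onto it is a full perspective (divergent) projection through the
source. A couch-angle field exists as a configuration hook but only 0° is
implemented.

## Dose engine (FCBB)

Per-beam dose is the product of three separable factors, linear in fluence:

* **Fluence term** — the fluence map at the isocenter plane convolved with a
  single isotropic 2D Gaussian penumbra kernel, σ = 3 mm, truncated at 4σ
  and discretely normalized. A one-Gaussian penumbra is the minimal model
  that produces realistic falloff; the width is configurable.
* **Depth term** — a percentage-depth-dose (PDD) lookup at the radiological
  depth from the source, computed as a trilinear line integral of density at
  one-voxel steps (midpoint rule) along the source→voxel segment clipped to
  the grid box. The default PDD is a synthetic 6 MV-like curve — linear
  build-up from the surface to d_max = 15 mm, then exp(−μ(d−d_max)) with
  μ = 0.005 mm⁻¹, tabulated at 1 mm and linearly interpolated. It is a
  documented stand-in for commissioning data and fully configurable.
* **Inverse-square factor** — `(SAD/r)²`, on by default, with a toggle
  because broad-beam formulations differ on whether it is included.

Dose is computed only for voxels inside the body and is zero outside.
Density defaults to the binary body mask (1 inside, 0 outside), consistent
with the deliberate exclusion of CT input from the channel design; a density
grid hook exists for heterogeneous phantoms.

Conformal apertures are built by casting the divergent ray through each
fluence-pixel centre and testing intersection with the target mask (linear
mask interpolation, 0.5 threshold, half-voxel sampling step), then dilating
with a disk of the isotropic margin (default 5 mm). For SIB plans the
aperture conforms to the union of all target masks, since the aperture must
cover every prescription level. Fluence pixels default to 2 mm for
beam-trace apertures and 5 mm for optimization beamlets (coarser to bound
problem size).

The fluence→dose map per beam precomputes the projection coordinates, depth,
PDD and inverse-square factors for all body voxels, so applying the operator
is a convolution, a bilinear interpolation and a scaling; the adjoint runs
the same steps backwards (bilinear splat, symmetric-kernel correlation) and
satisfies the inner-product identity to machine precision, which the
optimizer relies on.

## Input channels

* **Prescription** — per-voxel prescription of the highest-dose covering
  target, normalized by the maximum prescribed dose `dp_max`; SIB plans
  yield discrete levels equal to prescription ratios.
* **Avoidance** — OAR voxels take their avoidance weight (default 1 for all
  OARs), body voxels 0.1, outside 0; overlapping OARs take the maximum
  weight. Target∩OAR voxels follow the `overlap_policy`: the default
  `target_priority` removes them from the avoidance set (they carry the body
  value 0.1, since targets lie inside the body), prioritizing coverage;
  `oar_priority` keeps the OAR weight — the patient-specific adjustment that
  trades target coverage for sparing. Weights should remain consistent
  between training and inference.
* **Beam trace** — each beam's conformal-aperture unit-fluence dose is
  normalized by its own maximum before the sum is divided by the beam count.
  The per-beam max-normalization is an interpretation choice: it guarantees
  the map peaks near 1 where beams overlap regardless of depth or
  prescription, which bare unit-fluence doses would not. Identical beams are
  computed once and weighted by multiplicity, making the map bit-identical
  under beam duplication and invariant under permutation; it is equivariant
  under 90° axial grid rotations with correspondingly rotated gantry angles.

## Fluence-map optimization

Both modes minimize sums of one-sided quadratic penalties over the linear
dose operator, subject to non-negative beamlet intensities, by projected
gradient with a Barzilai–Borwein step, monotone backtracking (halving), and
a curvature-bound initial step. The solver is deterministic from zero
initialization; it stops at relative objective change < 1e-6 (configurable)
or the iteration cap. Residuals are normalized by the maximum prescription
(planning) or the reference maximum (reference mode), so the objective is
dimensionless and positively homogeneous: scaling prescriptions or the
reference by c scales the optimum by exactly c.

*Planning mode* (label synthesis): per-target mean one-sided underdose
(weight 100) and overdose (25) about the prescription, with nested boosts
claiming their voxels exclusively; OAR overdose above 0.1·Rx_max (weight 5 ×
the OAR's avoidance weight); body overdose above 0.6·Rx_max (weight 2). The
weights were chosen so that uncomplicated phantoms reach target D95% within
5% of prescription while keeping OAR/body penalties active; they are
ordinary planning knobs, exposed in `ObjectiveConfig`.

*Reference-guided mode* (feasibility probe): underdose below the reference
is penalized on the reference's support — the targets plus all voxels with
reference ≥ 5% of its maximum — and overdose above the reference everywhere
in the body. Restricting the underdose penalty to targets alone leaves
beam-path dose unconstrained from below and fails to reproduce achievable
references; with the support-wide penalty the objective is zero iff the dose
matches the reference on its support and nowhere exceeds it, so any
engine-generated reference is exactly recoverable. This surrogate plays the
role of a reference-guided planning engine as a feasibility probe only; it
does not model machine constraints, MLC sequencing or delivery-time effects.

## Synthetic phantoms

The generator emulates the *plan-parameter* heterogeneity of a real IMRT
cohort, not its anatomy: a convex ellipsoidal body; one spherical target
(optionally with a nested boost at half radius — SIB probability 0.3, boost
ratio 0.75–0.9, cf. typical 70/56 Gy pairs); 1–3 spherical/cylindrical OARs
placed near the target, overlapping it at a configurable rate (default 0.2)
to exercise the overlap-relabeling workflow; 5–25 coplanar beams, equispaced
or uniformly random; prescriptions uniform over 4–79.2 Gy. The default grid
is 64³ at 2 mm (a 12.8 cm cube); unit tests use smaller grids (8³–32³) to
keep the suite fast, and the sizes are stated in each test. Everything is
deterministic from the spec seed, and cohorts derive per-case seeds from one
master seed. Label doses come from planning-mode FMO through the same
engine.

Because body and phantoms are geometrically simple and density is binary,
passing tests demonstrate correctness of the encoders, engine, optimizer and
metrics and internal consistency of the full pipeline — not clinical
prediction accuracy on real patients, which would require real contours, CT
density and clinically approved plans.

## Predictor

A fixed compact 3D U-Net: two 3×3×3 convolutions + ReLU per resolution
level, average-pool downsampling, nearest-neighbour upsampling with skip
concatenation, and a linear 1×1×1 head; default 3 levels at base width 16
(unit tests and the scaled study use 2 levels at width 8). Forward, backward
and Adam are implemented directly in numpy (channels-last, 27-shifted-matmul
convolutions), so training is bit-deterministic given the seed and needs no
GPU. Training minimizes the Huber loss (δ = 1) on dose normalized by
`dp_max` — the output-normalization convention mirrors the prescription
channel, and Gy output is recovered by multiplying back; negative outputs
are clipped at inference. Augmentation is mirroring only (random axial
flips). Checkpoint selection keeps the best validation-loss epoch; a
non-finite loss aborts training and retains the last good checkpoint.
Default budget is 100 epochs at learning rate 1e-3; the scaled-down studies
in the test suite use 30–40 epochs on cohorts of ~20–50 cases, sizes chosen
as a deliberate desk-scale working point and stated where used.

## Metrics

*Gamma*: global normalization by the reference maximum; 10% low-dose
threshold applied to the reference; evaluated dose trilinearly interpolated
on a search lattice of step dta/10 within radius 3·dta. The implementation
visits offsets in order of increasing distance and retires a voxel once the
distance penalty alone exceeds its current best γ, which is exactly
equivalent to exhaustive search within the radius (verified against a dense
brute-force oracle). In each reported comparison the second-named dose is
the reference ("pred vs opt" → opt is reference); both the member choice and
the normalization are conventions, configurable.

*Dx%*: descending sort, value at rank ⌈x/100·n⌉, no interpolation — exact on
integer-valued oracles. Reports emit D2%, D5%, D50% and D95% for every
structure, covering both near-max and median OAR summaries and target
coverage. DVH curves are cumulative with a configurable bin (default
0.1 Gy) and agree with Dx% at every sampled level within one bin. MAPE
normalizes absolute Dx% deviations by the per-case prescription.

## Known limitations

- The PDD, penumbra width and inverse-square toggle are stand-ins for
  machine commissioning data; absolute dosimetry is not modelled.
- Homogeneous (binary) density only by default; no
  convolution/superposition heterogeneity correction.
- FMO is a beamlet-based surrogate without machine constraints; deliverable
  MLC sequences and final dose calculation are out of scope.
- Phantoms make no claim of matching any clinical cohort's anatomy
  distribution — only its plan-parameter ranges.
- Arc therapy and non-coplanar couch angles are not supported (couch field
  is a hook only).
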