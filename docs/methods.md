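# Methods

This note records the models, numerical choices and limitations behind
`limbarch`, in the spirit of a package methods appendix. Everything stated
here about accuracy is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external data.

## Coordinate and rasterization conventions

All grids are axis-aligned with voxel spacing `(dx, dy, dz)` in mm; a voxel
`(i, j, k)` has its center at `((i+0.5)dx, (j+0.5)dy, (k+0.5)dz)`. Axial
slices run along z. Phantom rasterization uses the center-sampling rule — a
voxel is foreground when its center lies inside the analytic solid — which
makes every generator deterministic and gives area/volume errors that
shrink with the pixel pitch (checked on the perturbed tube at 0.3 and
0.15 mm).

## Synthetic phantoms

The generators produce the study conditions the pipeline is designed for:

* **Fascia tube** — an irregular thin tube mimicking the deep (crural)
  fascia: band thickness about 1 mm on a 0.3 x 0.3 x 3 mm grid. Thickness
  and centerline radius are low-order Fourier series in polar angle; phases
  may be drawn from the seed, and an optional per-slice phase drift rotates
  the pattern through the leg (real fascia thickness variation is not
  translation-invariant along the limb; identical slices would also defeat
  across-slice averaging of discretization effects). Because integer
  harmonics integrate to zero over a full turn, the analytic mean thickness
  is independent of phases and drift — it is the constant term times the
  slice-average of the optional slice envelope.
* **Labeled limb** — disjoint ellipsoidal cylinders with exact analytic
  volumes on a 0.5 x 0.5 x 5 mm grid; semi-axes are derived from the
  requested volume so the rasterized voxel sum lands within ~2 %.
* **Unipennate muscle** — a volume-preserving sheared prism whose oblique
  end faces are parallel to the fiber direction `(sin a, 0, cos a)`, playing
  the role of the aponeuroses. Every fascicle therefore spans the full
  aponeurosis separation `Lx` and has length `Lx / sin a` exactly, which is
  the closed-form truth the recovery tests use. A plain box would clip
  fascicles near its ends and make the mean length truth ill-defined. All
  foreground voxels carry one tensor; the default eigenvalues
  `(2.1, 1.6, 1.4)e-3 mm^2/s` are typical of skeletal muscle (FA about
  0.21). The strongly prolate case `(1.5, 0.3, 0.3)e-3` (FA about 0.77)
  appears only as a closed-form FA/MD oracle — its anisotropy is far above
  muscle and above the tracking FA ceiling.
* **DWI simulation** — monoexponential tensor signal
  `S = S0 exp(-b g'Dg)` with one b = 0 volume, 20 directions on a Fibonacci
  hemisphere, b = 500 s/mm^2. Noise, when requested, is Rician (Gaussian on
  two quadrature channels, magnitude taken), the standard magnitude-MRI
  model. Zero noise plus the log-linear fit recovers tensors to ~1e-12
  relative, so the DWI round trip is a genuine identity test.

What the phantoms do **not** emulate: anatomy (organ shapes, multiple
tissues, partial-volume mixtures), scanner artifacts (eddy currents, B0
inhomogeneity, motion), non-Gaussian diffusion, and intra-muscle fiber
curvature or dispersion. Passing tests therefore demonstrate correctness of
the measurement algorithms under known geometry, not robustness to
real-scan confounds; preprocessing of real DWI (denoising, distortion and
motion correction) is assumed done upstream.

## Volumetry

Volumes are exact integer voxel counts times the voxel volume, converted to
cm^3. Registration is deliberately reduced to integer slice alignment on a
user-supplied bony landmark followed by trimming to the common z range — no
resampling — because visual-inspection registration is not reproducible
programmatically, and partial limb coverage means only the common trimmed
range is comparable. Percent changes are signed (negative = loss); report
tables additionally render the unsigned "loss of x %" phrasing. Compartment
changes are recomputed from summed volumes, never averaged from member
percentages (a compartment of 10+10 going to 9+12 is +5 %, not the mean of
-10 % and +20 %). A bundled table maps the standard calf compartments
(superficial posterior, anterior, deep posterior, lateral) and thigh
compartments (anterior/quadriceps, posterior/hamstrings, medial) to their
member muscles.

## Fascia thickness

Processing is 2-D per slice, matching how thin-sheet anatomy is read in
axial stacks. Per slice:

1. the band's one-pixel skeleton is extracted (`skimage.morphology.
   skeletonize`) and spur branches up to 5 pixels long are pruned by
   iterative endpoint removal (closed loops survive; the default suppresses
   rasterization spurs without eroding the main loop);
2. at each retained centerline pixel a local tangent is estimated from the
   5 x 5 neighborhood second moments; two rays are cast along the +/-
   normal; each boundary is located as the 0.5 crossing of the bilinearly
   interpolated band indicator (marching step half a pixel, then bisection);
   the two distances sum to the local thickness — the distance from the
   middle line to the inner plus the outer boundary.

The sub-pixel boundary localization matters: a voxel-quantized distance
transform doubled at the skeleton wobbles by up to +-0.08 mm with grid
alignment on bands only 3-4 pixels wide (exactly the fascia regime), which
is material when detecting ~9 % thickness shifts. The normal-crossing
estimator's bias, measured on constant-thickness annuli from 0.75 to
1.5 mm, stays below 0.02 mm and within one pixel pitch at both 0.3 and
0.15 mm resolution. Rotating a phantom slice by 37 degrees changes the
global mean by under 5 %, confirming near-isotropy.

Centerline arclength uses Kulpa's corrected chain weights (0.948 per axial
step, 1.343 per diagonal step, diagonal steps that shortcut an axial pair
excluded), which brings digital circle circumference within ~0.5 % of
analytic. The algebraic mean `V / (L * W)` excludes empty slices from the
width `W` (an empty slice contributes neither volume nor arclength, so
including it would only deflate the estimate). Algorithmic and algebraic
means agree within a few percent on all shipped phantoms (15 % is the
accepted concordance bound).

Histograms use fixed-width bins from zero (default 0.05 mm) and conserve
sample counts. Shift reports give mean and median percent change; note the
median of a nearly-quantized distribution moves in coarse steps, so the
mean shift is the primary statistic. A threshold segmenter on dual-echo
subtraction images ships for demonstrations only; quantification assumes an
expert (or phantom) mask.

## DTI architecture

**Tensor fit.** Log-linear least squares per voxel for the six unique
tensor components plus `ln S0`, requiring at least 7 volumes and exactly one
b = 0 volume. Voxels with any non-positive sample are flagged invalid and
excluded downstream rather than fitted through a log of zero.

**Tracking.** Fixed-step Euler integration (1 mm) along the principal
eigenvector, bidirectional from seeds drawn uniformly inside the gated
region, eigenvector sign chosen for continuity with the previous step.
Stopping conditions: leaving the trackable region, FA outside [0.05, 0.6]
(muscle FA is low; the ceiling rejects artifactual voxels), a per-step
turning angle above 30 degrees, or 200 mm of length; tracts under 5 mm are
discarded. Two numerical details matter for accuracy:

* the trackable region is the 0.5 level set of the *trilinearly
  interpolated* gated-voxel indicator, and the final boundary crossing is
  located by bisection to 0.1 mm and appended — nearest-voxel membership
  would both alias the stopping surface and lose up to a step per end;
* seeds come from the mask eroded by one voxel (partial-volume avoidance,
  as in standard tractography practice). Without erosion, fibers running
  parallel to an oblique boundary within half a voxel weave through the
  rasterized surface and terminate early; at 15 degrees pennation this
  biased mean fascicle length low by ~15 %.

Seeding repeats until the target count (default 1000) is accepted or the
attempt budget (50 000) is exhausted, which logs a warning and returns the
partial set. Identical seeds give bit-identical tract sets.

**Extrapolation.** Each coordinate is fitted as a cubic polynomial of
arclength (cubic captures curved fascicles without oscillation) and the
curve is marched outward in half-step increments until it crosses the mask
surface (bisection to 0.1 mm), capped at 50 % of raw length per end; a
cap hit rejects the tract with reason `no-boundary`, fewer points than the
polynomial needs rejects it as `short`. The inclusion filter then keeps
extrapolated tracts with total extension at most 30 % of raw length and
final length within 5-200 mm; every rejection carries exactly one reason,
and seeded = accepted + rejected.

**Metrics.** Fascicle length is the polyline arclength (cm); the fascicle
vector is the unit chord between endpoints (one vector per fascicle, not
per-segment tangents); pennation is `arccos` of the absolute dot product
with the muscle's line of action, folding arbitrary tract orientation into
[0, 90] degrees. The line of action is the principal axis of the voxel
coordinate cloud, sign-oriented to +z; note that for strongly sheared
geometries this PCA axis differs from the anatomical long axis, so the
phantom tests pass the known line of action explicitly. PCSA = volume /
mean fascicle length holds exactly as stored.

Measured recovery (noiseless, angles 15-60 degrees): pennation exact to
machine precision, mean fascicle length within 0.7 %, PCSA identity to
1e-15. With Rician noise at SNR 30, mean pennation stays within 0.5 degrees
of truth over five seeds (5 degrees is the accepted bound).

## Orchestration

`RunConfig` is a flat YAML-serializable dataclass holding every tunable
once (stage toggles, paths, landmark indices, fascia parameters, tracking
parameters, per-stage seeds); `load(save(c)) == c`. `run_comparison` chains
volumetry, fascia and DTI per toggle, writes per-stage TSV/JSON artifacts
plus a comparison report with a provenance block (config hash, seeds,
package version), and aborts with the stage name and offending input on any
stage error. Reruns with the same config are bit-identical.

Preprocessing offers the conventional slice-wise denoise-then-smooth pair:
an adaptive (local-statistics) Wiener filter and a normalized binomial
Gaussian, both 3 x 3 by default, both with reflective boundaries so
constants pass through unchanged and interior impulse mass is conserved;
kernel size 1 is the identity, even sizes are rejected.

## Problem sizes

Tests and the acceptance script run the tube phantoms at 10 slices
(0.3 mm and 0.15 mm pitch), the pre/post pair at the default fascia/limb
grids, and the pennate phantoms at 2 mm isotropic spacing with 150-200
tracts per muscle — sizes chosen so the full suite completes in well under
a minute while every estimate remains comfortably inside its tolerance.
Tract targets are configurable up to the default 1000 used for real-scale
muscles.

## Known limitations

* Slice alignment is integer-only; sub-slice offsets between time points
  appear as volume noise of up to one slice at the trimmed ends.
* The thickness pipeline assumes one dominant thin band per slice; touching
  or branching sheets would need explicit component handling.
* Tractography is single-tensor and deterministic; crossing-fiber regions
  and probabilistic uncertainty are out of scope.
* The PCA line of action is a geometric, not anatomical, axis; for muscles
  whose mechanical line of action deviates from the voxel-cloud principal
  axis, supply the vector explicitly.
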