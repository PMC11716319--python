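# limbarch

Quantification of longitudinal skeletal-muscle and deep-fascia change from
labeled MRI volumes. The package targets the measurement problem of pre/post
immobilization studies of the lower limb: given segmented masks from two
imaging time points (and, optionally, diffusion-weighted stacks), it reports

* **muscle and bone volumes** per label and per anatomical compartment, with
  signed percent changes after landmark-based slice alignment
  (`limbarch.volumetry`);
* **deep-fascia thickness distributions** from a thin-sheet centerline
  algorithm, with an independent algebraic cross-check and pre/post shift
  detection (`limbarch.fascia`);
* **muscle architecture from DTI** — fascicle length, pennation angle and
  physiological cross-sectional area (PCSA) — via tensor reconstruction,
  deterministic fiber tracking and polynomial extrapolation of tracts to the
  muscle boundary (`limbarch.dti`).

Because suitable in-vivo datasets are rarely shareable, `limbarch.phantoms`
generates synthetic inputs with closed-form ground truth (irregular fascia
tubes, labeled limb solids, unipennate fiber fields with simulated DWI), so
every stage of the pipeline is testable end to end without scan data.

## The measurements

**Volumetry.** A label's volume is its voxel count times the voxel volume.
Compartment volumes are exact sums of member labels, and percent changes are
always computed sum-then-ratio: `100 * (post - pre) / pre`.

**Fascia thickness.** The fascia is modeled as an irregular thin tube. Slice
by slice, the binary band is reduced to its one-pixel middle line
(topological skeleton, spur-pruned). At each centerline pixel the distances
from the middle line to the inner and the outer boundary are measured along
the local band normal — boundaries located at sub-pixel precision on the
interpolated indicator — and summed into a local thickness sample. Pooled
samples across slices form the thickness distribution; the histogram and the
mean/median shift quantify pre/post thickening. The cross-check estimates
mean thickness algebraically as `V / (L * W)` with `V` the segmented volume,
`L` the mean per-slice centerline arclength and `W` the slab width (number
of non-empty slices times slice thickness).

**DTI architecture.** Per voxel, the diffusion tensor `D` solves
`ln S(g) = ln S0 - b * g' D g` by least squares; FA and MD follow from its
eigenvalues. Fibers are tracked deterministically (fixed-step Euler along
the principal eigenvector, bidirectional from uniform seeds, stopping on
mask exit, FA gate, turning-angle limit or length ceiling). Tracts that stop
short of the muscle surface are extended by fitting each coordinate as a
cubic polynomial of arclength and marching the fitted curve to the boundary;
tracts whose extended length exceeds 1.3x their raw length, or falls outside
5-200 mm, are excluded. Then, per muscle:

* fascicle length = polyline arclength of the extrapolated tract,
* pennation angle = `arccos(|fascicle chord . line of action|)`,
* PCSA = muscle volume / mean fascicle length.

## Worked example

A 30-degree unipennate muscle phantom (20 mm aponeurosis separation, so the
true fascicle length is 20 / sin 30 = 40 mm), simulated at b = 500 s/mm^2
with 20 gradient directions and recovered by the full pipeline:

```python
import numpy as np
from limbarch import dti, phantoms

mask, tensors, truth = phantoms.make_pennate_phantom(
    box_dims_mm=(20, 20, 30), pennation_angle_deg=30.0,
    eigenvalues=(2.1e-3, 1.6e-3, 1.4e-3), spacing=(2.0, 2.0, 2.0),
)
dwi = phantoms.simulate_dwi(tensors, phantoms.twenty_direction_table(), b_value=500.0)
field = dti.fit_tensors(dwi, mask.binary())
tracts = dti.track_fibers(field, mask.binary(), dti.TrackingParams(target_count=200), seed=1)
tracts = dti.filter_tracts(dti.extrapolate_tracts(tracts, mask))
report = dti.architecture_metrics(tracts, truth.line_of_action, truth.muscle_volume_mm3 / 1000)
```

which prints, via the fields of `report`:

```
pennation 30.00 deg (truth 30.0)
fascicle length 3.991 cm (truth 4.000)
PCSA 3.007 cm^2, volume 12.0 cm^3, accepted 200
```

The pennation angle is recovered exactly (the noiseless tensor field is
uniform), the mean fascicle length is within 0.3 % of the analytic chord,
and PCSA times mean fascicle length reproduces the volume by construction.

The same pipeline is available from the shell. For fascia, for example:

```bash
limbarch simulate fascia --seed 5 --out demo/
limbarch fascia --mask demo/fascia_mask.nii.gz --out demo_results/
```

reports a mean thickness of 0.993 mm against the phantom's analytic 1.0 mm
(algebraic cross-check 0.992 mm, 4720 centerline samples). `limbarch
volumes`, `limbarch fascia-compare`, `limbarch dti` and `limbarch run
--config` cover the remaining stages; `limbarch run` chains them into a
single pre/post comparison report with provenance.

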