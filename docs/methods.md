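# Methods

## The measurement problem

In asymmetric stem-cell division the cleavage furrow forms toward the basal
pole, so the contractile ring bisects the cell into a large apical daughter
and a small basal daughter (here called the GMC, ganglion mother cell,
after the fly neuroblast lineage). The quantities this package measures
from a single-plane, single-channel cortical-myosin movie are:

1. the **cortical enrichment index** `(Myo_cortex − Myo_cyto)/Myo_cyto`,
   evaluated on the polar cortex (excluding the furrow) at the frame of
   maximal polar signal — in these cells a transient myosin pulse on the
   polar cortex peaks near 80 % furrow ingression;
2. the **cortex-to-furrow ratio** of mean cytoplasm-subtracted linescan
   intensity outside vs inside the furrow segment, where the furrow segment
   is the contour stretch whose tangent diverges less than 30° from the
   apico-basal long axis;
3. **percent ring constriction** `100·(d0 − d)/(d0 − d_mb)`, 0 % at
   anaphase onset and 100 % when the ring reaches midbody size (default
   4 px, the midpoint of a typical 3–5 px midbody);
4. the **furrow basal distance** — projection of the furrow midpoint onto
   the long axis, measured to the basal pole — and its correlation with
5. the **final GMC area** (ROI pixel count × pixel size²) and **roundness**
   `4A/(πL²)` with `L` the maximal chord of the region.

## Synthetic movie generator

The generator provides ground truth for every read-out. It is a geometric
photometric phantom, not a mechanical simulation.

**Geometry.** The cell starts as a disk of radius `R = 5.5 µm` (a large
neuroblast, ~11 µm across). From ingression onset the outline is an axial
half-width profile `w(y)`: an apical lobe and a basal lobe of the family
`w(u) = (d/2)·u + B·√u·(1 − u)` (`u` = 0 at the pole, 1 at the furrow),
joined by a short straight-walled bridge of length 0.8 µm — the
intercellular-bridge geometry of late telophase. `B` is set in closed form
so each lobe's cross-section area is exact. The basal lobe area is
prescribed as the circular-segment area of the initial disk cut at the
current furrow offset `δ(t)`, the apical lobe takes the complement, so
total area is conserved and the final daughter size is an analytic function
of where the furrow ends. The profile is smoothed axially (σ = 0.15 µm)
with the furrow half-width re-pinned to exactly `d(t)/2`, and the small
area lost to smoothing is restored by one proportional re-targeting of the
lobe areas.

**Schedules.** The ring diameter `d(t)` is flat at `d0` (by default the
disk chord at the initial furrow plane) until ingression onset, declines
linearly to `d_mb` at the midbody frame, then stays flat; the constriction
fraction `c(t)` therefore hits exactly 0 and 1 at the scheduled frames.
The polar myosin pulse is `E(t) = E·exp(−(c(t) − 0.8)²/(2·0.15²))`; only
its peak position (~80 % ingression) is biologically anchored, the width
0.15 (in constriction fraction) is a modelling default. With
`correction_on=False` the furrow stays at its initial offset `δ0`, so the
final GMC area grows strictly with `δ0`; with `correction_on=True` the
offset drifts by a smoothstep in `c(t)` toward the offset whose segment
area equals `target_gmc_area` (default π·(2 µm)²), making the final size
independent of `δ0`. These are the two regimes whose contrast the
correlation experiment detects.

**Photometry and noise.** Cytoplasm 120 a.u.; a cortical band of width
0.8 µm at cytoplasm + 300 a.u.; a contractile-ring bump of 400 a.u. with
arclength σ = 4 % of the perimeter, centred on the two furrow points; the
polar pulse adds `E(t) × 300` uniformly on the band. Frames are rasterised
with 8× supersampled coverage so the half-maximum of a rendered edge falls
on the true boundary (a binary mask would dilate every structure by half a
pixel), blurred with a Gaussian PSF of σ = 0.1 µm (the diffraction limit of
a 1.4 NA objective at ~515 nm), then Poisson shot noise, a constant camera
offset of 100 a.u., and Gaussian read noise (σ = 3) are applied, the EMCCD
approximation. Pixel size 0.16 µm, frame interval 20 s, 16 frames with
anaphase onset at frame 1, ingression onset at 3 and midbody at 13 (a
~4-minute cytokinesis). Identical parameters and seed give byte-identical
movies.

## Measurement conventions

**Outline tracing.** Frames are Gaussian-smoothed (σ = 1 px), Otsu
thresholded, the largest component contoured by marching squares, and each
vertex refined to the intensity-gradient maximum along its normal — the
unbiased edge position under symmetric blur, which matters most where the
local plateau is much brighter than the global threshold (the cortical band
around a nearly closed furrow). The contour is resampled to 200 uniform
arclength samples and lightly smoothed (σ = 1.5 samples). Poles are the
contour points extremal along the principal axis of the region; the pole
with the smaller row is labelled apical.

**Furrow and ring diameter.** The furrow point on each lateral side is the
sample of maximal concave curvature (local circle fit over 11 samples,
concavity threshold 0.05 px⁻¹); ingression onset is the first frame with a
furrow on both sides. The ring diameter is *not* the distance between
those two points: at near-closure the traced outline cannot descend into
the bright merged neck. Instead the intensity profile is sampled
perpendicular to the long axis at the furrow plane, and the diameter is the
distance between the outer half-maximum crossings — exact for a blurred
step edge at any neck width — minimised over nearby rows (the waist). The
same width scan refines the furrow's axial position to the interior local
width minimum nearest the curvature estimate, since on an asymmetric neck
the curvature extremum sits a pixel or two off the true waist. `d0` is
measured on the anaphase-onset frame as the cell width at the (refined)
furrow plane of the onset frame — the ring does not exist at 0 %, so a
geometric proxy is required, and the pre-furrow cell is too round for its
own principal axis to be reliable.

**Constriction curves** are made monotone by a running maximum after onset
(constriction cannot reverse) and smoothed with a centred moving average of
2 neighbours per side, applied only from onset (the flat pre-onset baseline
is exact by definition) with odd-reflection padding so a linear ramp is
smoothed without end bias. The "6 neighbours average" of linescan plots is
read as a symmetric 7-point window (3 per side) and exposed as `smooth_k`.

**Linescans** follow one lateral side of the contour from apical to basal
pole (default: the side with the higher mean signal), sampling the mean of
`width_px = 2` bilinear samples along the inward normal, centred 2.5 px
inside the boundary so the line rides the middle of the cortical band.
Cytoplasm is the region eroded clear of the band (band width + 2 px);
cytoplasm subtraction retains negative values, only the camera-offset
subtraction clips at zero. Max-normalisation is applied before smoothing,
so the pre-smoothing maximum is exactly 1.

**Daughter measurement.** The GMC region is the cell polygon cut by the
chord through the measured waist edge points, taking the piece containing
the basal pole; area is the rasterised pixel count × pixel size². The
final area and roundness are the medians over the last (up to three)
furrowed frames, which damps occasional waist-localisation jumps on noisy
frames. Roundness uses the standard area/major-axis form `4A/(πL²)`; the
major axis is the exact maximal pairwise distance between hull vertices.

**Statistics.** Mann–Whitney U is two-tailed with 0.5 tie credit: exact
(full enumeration of the null) when the combined sample size is ≤ 20 and
tie-free, otherwise the normal approximation with tie-corrected variance
and continuity correction (`scipy.stats.mannwhitneyu` supplies both
branches; the test suite checks the exact branch against an independent
enumeration oracle). Pearson r uses the t-transform two-tailed p; quartiles
are linear-interpolation (type 7), recorded because IQR bars depend on the
convention. No multiple-comparison correction is applied; p values are
reported per comparison.

**Isoform usage.** With junction counts `c_j` and the 0/1 junction×isoform
membership matrix `M`, frequencies solve `min ‖c − M(λf)‖²` s.t. `λf ≥ 0`
by NNLS, then normalise to sum 1. The estimator choice (NNLS with a free
global scale) is this package's own; under uniform read coverage the
expected junction count is proportional to `(M f)_j`, which is also the
sampling model of the bundled simulator. Junctions observed but absent
from the model are reported as novel, never dropped; isoforms with
identical junction signatures are flagged non-identifiable. The bundled
six-isoform example model is synthetic (see `examples/`): it reproduces the
structural features of a gene with a cassette exon shared by two isoforms,
alternative first/last exons, and a distinct junction signature per
isoform, not any real annotation.

## What the phantom does and does not show

Passing tests on the phantom demonstrate that the measurement pipeline
recovers known geometry and photometry through a realistic imaging chain
(diffraction blur, shot/read noise, camera offset, rasterisation). The
phantom does not model 3-D sectioning, photobleaching, cortical flows,
neighbouring cells, cell movement, or DIC channels; real movies add
segmentation failures and manual-annotation variance that no synthetic
test can certify. Two quantitative limits of the imaging physics surface
in the tests: beyond ~50 % constriction the exterior cleft at the furrow
is narrower than the PSF, so traced outlines deviate locally by up to 2 px
from the true boundary (the intensity-based waist measurement is immune to
this and stays within 1 px); and at 30-cell cohorts the correction-on R²
has an expected null tail, so roughly one in twenty replicates can exceed
an absolute R² bound of 0.2 by chance.

## Numerical choices

- Concavity threshold 0.05 px⁻¹ and an 11-sample curvature window: chosen
  for stability on 200-sample contours with subpixel jitter; both exposed
  as parameters.
- Midbody anchor 4 px (midpoint of 3–5 px); `clip_tol` 5 % relative
  overshoot before percent-constriction rejects a diameter.
- Waist-scan plateau tolerance 0.15 px: a flat bridge counts as one waist
  and its centre is the furrow plane; prominences below this are not
  called waists.
- Exact-vs-asymptotic Mann–Whitney switch at combined n = 20; ties always
  force the approximation.
- The Pearson-r-equals-one invariant for correction-off sweeps holds only
  approximately (r > 0.99): the segment area is monotone but mildly
  nonlinear in the furrow offset.
- Degenerate inputs reject loudly (empty erosion region, flat profiles,
  all-zero junction counts, self-intersecting contours, double background
  subtraction); detection functions return `None`/no-ingression rather
  than raising when the biology (a convex cell) rather than the input is
  at fault.

## Problem sizes

Default test and acceptance problem sizes: 16-frame 96×96 movies; 10 noise
replicates per polar-amplitude level (5 levels); 20 seeded replicates of
the correction contrast at 30 cells per cohort; the Mann–Whitney lattice
checks all sample-size pairs with combined n ≤ 12 (40 partitions per pair);
isoform recovery uses 5 Dirichlet draws at 10⁴ reads. These sizes keep a
full run in the minutes range on one CPU while leaving every statistical
margin comfortable.
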