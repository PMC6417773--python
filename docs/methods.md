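# Methods

## The segmentation problem

Intravascular optical coherence tomography (OCT) images a coronary artery
from inside: each frame (B-scan) is a cross-section assembled from radial
depth profiles (A-scans) around the catheter, and a pullback is the ordered
stack of frames acquired while the catheter is withdrawn at constant speed.
`octseg` detects, per frame, (i) the lumen contour and (ii) the cross-
sections of polymeric bioresorbable scaffold struts, which appear as
approximately rectangular regions with a dark core surrounded by a bright
rim (a "box"). Downstream uses are lumen/scaffold quantification and the
export of a 3D point cloud (lumen points and strut centroids at
`z = frame_index x frame spacing`) for vessel reconstruction.

Physical scale defaults to 15 um/pixel in-plane and 125 um between frames;
images are 8-bit grayscale.

## Per-frame pipeline

1. **Pre-processing** (`preprocess`). The calibration bar and the catheter
   disk are blanked (their location comes from configuration/metadata, not
   auto-detection). Before lumen segmentation only, residual blood speckle
   inside the lumen is suppressed by multiplying the frame with a binary
   mask built by (a) thresholding at the 0.85 quantile of the frame's
   intensity distribution, (b) morphological opening with a disk (default
   radius 2 px), (c) removing 8-connected components smaller than
   `min_area_px` (default 50 px).

   The quantile is computed over *all* pixels of the artifact-removed frame,
   zeros included, with the inclusive linear-interpolation definition. This
   is deliberate and configurable: the zero background shifts the 0.85
   quantile, and on frames where bright structure covers less than 15% of
   pixels the quantile degenerates to the background level and the
   threshold keeps everything. Real OCT frames (and the phantom, which
   renders a thick bright wall band) have enough bright tissue that the
   quantile sits at the tissue level.

2. **Lumen segmentation** (`lumen`). The masked frame is resampled on a
   polar (r, theta) grid about the catheter centre by bilinear
   interpolation (defaults: 360 A-scans, 1 px radial step, radii up to half
   the image diagonal — at or above Cartesian resolution). A radial
   derivative kernel `[-1, 0, 1]` is applied per A-scan; only positive
   (dark-to-bright) responses qualify. The first radius whose response
   reaches 30% of that A-scan's maximum is the raw lumen edge. The kernel
   is applied without cross-A-scan smoothing on purpose: a fully shadowed
   A-scan (guide wire) must come out *missing* rather than borrow its
   neighbours' edges. Missing A-scans are filled by a periodic cubic
   smoothing spline over theta (default smoothing 0, i.e. interpolating);
   gaps wider than 120 degrees trigger a warning. Per-A-scan normalisation
   of the edge response (rather than one global threshold) makes the tracer
   insensitive to the absolute brightness of the wall.

3. **Strut segmentation** (`stent`). Contrast is first enhanced with a
   gamma power law `I -> 255 (I/255)^0.6` (a 256-entry LUT, round-half-up).
   Core candidates are extracted as *holes*: threshold at the 0.85 quantile
   of the enhanced frame, morphological closing with a radius-1 element,
   flood-fill of enclosed holes, and Boolean subtraction of the pre-fill
   image — only pixels enclosed by bright boundaries remain. The closing
   uses the Chebyshev unit ball (3x3 block): the 4-connected diamond of the
   same radius provably cannot seal a 1-pixel rim gap, which is the
   closing's purpose here. Gaps of several pixels ("open-box" struts)
   still defeat the flood fill; this is a known limitation of box-based
   detection, quantified below.

   False positives are then removed in two stages:
   * **Area constraint**: regions must have 10 <= area <= 300 px
     (inclusive bounds; the whole-lumen "hole" produced by a closed wall
     ring is rejected here).
   * **Region of maximum likelihood**: the intersection of the lumen
     contour dilated by a 20 px disk with a *reference line* dilated by a
     5 px disk. The reference line is a periodic smoothing spline through
     the centroids of a rough segmentation (hole extraction without gamma
     or closing, then opening with a radius-3 disk — low sensitivity, high
     specificity) pooled over the adjacent frames (window +-1, truncated at
     pullback ends). With fewer than 4 pooled centroids the lumen contour
     itself serves as reference line. A candidate is kept iff its centroid
     lies inside the mask; centroid membership is robust to partial
     clipping of a region at the band edge. Dilations are computed exactly
     via the Euclidean distance transform.

   The reference-line spline uses light smoothing (s = 2 per centroid).
   Strut centroid radii legitimately vary around an eccentric lumen;
   heavier smoothing flattens the spline toward a circle and can push it
   more than the 5 px band away from true struts, silently deleting them.

4. **Strut-based lumen correction** (`correction`). At baseline the
   abluminal face of a well-apposed strut lies on the lumen wall, so the
   first-edge tracer stops at the strut's inner rim (or at blood residue in
   front of it) and bites into the lumen. Contour and strut masks are
   rendered in polar coordinates, the strut mask is dilated with a 1x10
   (radial x tangential) rectangle — implemented as +-5 A-scan columns with
   wrap-around — and per A-scan the corrected radius is the maximum of the
   traced radius and the outermost strut pixel. The corrected radii are
   re-fit with the same periodic spline as the original contour so pre- and
   post-correction contours stay comparable; since every A-scan is a knot
   and the default smoothing is 0, the outward-monotonicity guarantee
   (corrected >= traced wherever a dilated strut crosses the A-scan) holds
   exactly, and re-correcting is a fixed point to within 0.5 px. The
   correction is a configuration flag: on for baseline acquisitions, off
   for follow-up imaging where struts are covered by neointima.

## Pullback quality classification (`quality`)

The number of struts visible per frame depends on the scaffold design and
is well modelled as Gaussian across frames. Its mean and SD are the sample
statistics of reference counts (manual segmentation or phantom ground
truth; at least 10 frames, zero variance rejected). A frame is 'poor' iff
its detected-region count is strictly below the 5% quantile of that
Gaussian — the detector evidently missed the expected struts. A pullback is
'poor' iff strictly more than a threshold number of frames are poor; the
threshold is 10 frames, or equivalently 20% of the frames considered, and
the integer form wins when both are configured. Both strictness choices
are boundary-tested.

## Validation metrics (`metrics`)

Lumen masks are compared pixel-wise: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP); zero denominators are *flagged* (None
with a warning), never silently 0. Struts are compared region-wise: an
automatic region is TP if it overlaps any reference region by at least one
pixel (paired with the maximally overlapping one; ties to the larger
index). Matching is deliberately not one-to-one — two automatic regions may
both be TPs against one reference region — with an optional strict
one-to-one greedy mode. Matched pairs yield the total centroid distance and
its radial component about the lumen centre (absolute value; the sign
convention is not fixed), in micrometres, with quartiles. Contours yield
per-A-scan |r_auto − r_ref| distances (the reference is resampled onto the
automatic theta grid if needed). Lumen areas use the shoelace formula on
the 360-vertex polygon (0.04% low for a circle at that vertex count);
self-intersecting polygons are rejected via a shapely validity check.
Area agreement uses Bland-Altman bias +- 1.96 SD limits and Pearson
correlation.

## The phantom (`phantom`)

The phantom renders the image *features the algorithm exploits*, with
exactly known ground truth — not OCT physics:

* dark lumen with a smoothly eccentric radius
  `r(theta) = R (1 + 0.5 e cos 2(theta - phase))`, a seed-independent
  low-order cosine modulation of R along the pullback (+-6%), and a slow
  per-frame rotation of the eccentricity axis;
* a thick bright wall band starting exactly at the lumen boundary, with a
  dimmer deep-tissue level beyond it (the wall band also keeps the 0.85
  intensity quantile at the tissue level, as in real frames);
* box struts: a bright rim (default 2 px) around a dark core, full box
  14 x 20 px (radial x tangential), placed with the abluminal face on the
  lumen boundary and penetrating 2 px into the wall so no spurious enclosed
  gaps form between rim and wall; angular positions are drawn without
  replacement from a uniform slot grid with a minimum separation, so
  regions never merge and region-wise matching is unambiguous; per-frame
  counts are Gaussian (default mean 9, SD 1.5), rounded and floored at 0;
* optional "open-box" defects: a contiguous rim arc of 30-50% of the rim
  pixels, centred on the adluminal side, is removed with the configured
  probability;
* optional blood-residual speckle: bright dots of 1-3 px at a configured
  density inside the lumen (the in-vivo speckle density of poor images is
  not quantified anywhere, so it is a free parameter, not a clinical
  claim);
* a catheter disk and a calibration bar, so artifact removal is exercised;
* optional Gaussian blur (sigma = 1 px), off by default — ground truth
  matches the rendered pixels exactly only in the unblurred case.

Identical specs produce bit-identical pullbacks; the per-frame RNG derives
from `(seed, frame_index)` so standalone frames equal their in-pullback
counterparts.

**What passing on phantoms does and does not show.** The phantom has
piecewise-constant intensities, no speckle texture in the wall, no
attenuation or strut shadowing, no metallic-strut blooming, no side
branches or bifurcations, and no neointimal coverage. Perfect strut
recovery on clean phantoms therefore verifies the *logic* of the pipeline
(morphology semantics, likelihood filtering, correction geometry), not
clinical-grade performance; on in-vivo 8-bit pullbacks the same design
trades sensitivity for precision, and open-box struts remain undetectable
by construction — the phantom's open-box sweep (sensitivity falls from 1.0
toward 0 as the open-box fraction goes 0 -> 1 while precision stays high)
reproduces that failure mode qualitatively.

## Numerical choices and degenerate inputs

* Quantiles: `numpy.quantile` linear interpolation over all pixels.
* Labelling: 8-connectivity throughout (masks, holes, regions).
* Periodic splines: `scipy.interpolate.splrep(per=1)`, cubic, with the
  first point appended one period up; duplicate angles are merged by
  averaging radii before fitting.
* Exact disk dilations via `scipy.ndimage.distance_transform_edt`.
* Constant-intensity frames: the noise mask warns and returns empty; the
  tracer then reports "no lumen found" and the pipeline marks the frame
  failed without aborting the pullback (a run fails only if every frame
  fails).
* Rough segmentation runs on the raw (not gamma-filtered) image —
  configurable (`rough_on_gamma`) since the original description is
  ambiguous — and applies the same area bounds (`rough_area_filter`,
  default on) so a closed wall ring cannot inject the whole lumen as a
  fake centroid.
* The even 10 px tangential dilation width of the correction is anchored
  symmetrically (+-5 columns).

## Problem sizes used by the shipped checks

The test suite exercises 512x512, 50-frame pullbacks at five seeds for
lumen recovery, 12-frame pullbacks per open-box condition for strut
degradation, and constructed scenes/oracles elsewhere; the whole suite runs
in about a minute. `scripts/acceptance.py` re-runs the pipeline on two
clean and two degraded 25-frame 512x512 pullbacks (seeds derived from
`--seed`) in ~20 s. These sizes are the package's own choice of a compact
but statistically meaningful study (about 450 struts and 50 lumen frames
per run).

## Known limitations

* Open-box struts with large rim gaps are undetectable by design; the
  quality classifier exists precisely to flag pullbacks where this
  dominates.
* The catheter position is taken from configuration, not estimated.
* No bifurcation/side-branch logic; the first-edge rule will follow the
  ostium contour.
* Strut detection assumes the polymeric box appearance; metallic struts
  (bright blob + shadow) are out of scope.
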