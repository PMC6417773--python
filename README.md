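# octseg

Automatic segmentation of intravascular optical coherence tomography (OCT)
pullbacks of coronary arteries treated with polymeric bioresorbable
scaffolds: per-frame **lumen contour** detection, **box-shaped strut**
detection, **strut-based lumen correction**, an automatic **pullback
quality** classifier, and the full validation-metric suite — plus a
synthetic phantom generator with exact ground truth, so the whole pipeline
is testable end-to-end without clinical data.

Intended users: researchers quantifying scaffolded vessels from OCT (lumen
area, strut counts/positions) or building patient-specific 3D vessel
models, for which the pipeline exports a labelled lumen/strut point cloud.

## Method

Each 8-bit frame (default scale 15 um/px in-plane, 125 um between frames)
is processed as:

1. **Pre-processing** — blank the calibration bar and catheter; build an
   intra-lumen noise mask by thresholding at the 0.85 quantile of the
   intensity distribution, opening with a disk, and removing small
   components; multiply it into the frame.
2. **Lumen** — resample to polar (r, theta) about the catheter centre
   (360 A-scans); per A-scan take the first radius where the positive
   radial gradient reaches 30% of that A-scan's maximum; fill missing
   A-scans with a periodic cubic spline; convert back to Cartesian. This
   yields one radius per A-scan, r(theta_k).
3. **Struts** — scaffold struts image as a dark core inside a bright rim.
   After gamma enhancement (I -> 255 (I/255)^0.6), cores are the *holes* of
   the thresholded image: threshold at the 0.85 quantile, close (radius 1),
   flood-fill, subtract. Candidates are kept if 10 <= area <= 300 px and if
   their centroid falls in the region of maximum likelihood — the
   intersection of the lumen contour dilated by 20 px with a reference
   line (a periodic spline through rough-segmentation centroids pooled
   over adjacent frames) dilated by 5 px.
4. **Correction** — render contour and struts in polar coordinates, dilate
   the strut mask by a 1x10 (radial x tangential) rectangle, and take per
   A-scan the outermost white pixel, so struts and blood residue no longer
   bite into the contour: r_corr(theta) = max(r(theta), r_strut(theta)).
5. **Quality** — per-frame strut counts are modelled as Gaussian(mean, sd)
   fitted on reference counts; a frame is *poor* iff its count falls below
   the 5% quantile, and a pullback is *poor* iff more than 10 frames (20%)
   are poor.

Validation follows the standard indexes — pixel-wise sensitivity
TP/(TP+FN) and specificity TN/(TN+FP) for the lumen; region-wise
sensitivity and precision TP/(TP+FP) for struts (any-overlap matching) —
plus per-A-scan contour distances, strut centroid total/radial distances,
lumen areas, and Bland-Altman / regression agreement. See
`docs/methods.md` for assumptions, parameter rationale, and limitations.

## Worked example

```python
import octseg as o

# synthetic pullback with known truth: 10 frames, 512x512, 15 um/px
spec = o.PhantomSpec(n_frames=10, seed=42)
pullback, truth = o.generate_pullback(spec)

segs, _ = o.run_pullback(pullback, o.run_config_for(spec))

tp = fp = fn = tn = rtp = rfp = rfn = 0
areas_auto, areas_true, dists = [], [], []
for seg, ft in zip(segs, truth):
    c = o.pixel_confusion(seg.contour.to_mask(pullback.frame_shape), ft.lumen_mask)
    tp, fp, fn, tn = tp + c.tp, fp + c.fp, fn + c.fn, tn + c.tn
    rc, _ = o.region_match(seg.struts, ft.strut_regions)
    rtp, rfp, rfn = rtp + rc.tp, rfp + rc.fp, rfn + rc.fn
    true_cnt = o.LumenContour(radius_px=ft.lumen_radius_px,
                              center_rc=seg.contour.center_rc)
    dists.extend(o.contour_distance(seg.contour, true_cnt))
    areas_auto.append(o.lumen_area(seg.contour))
    areas_true.append(o.lumen_area(true_cnt))

q1, med, q3 = o.distance_quartiles(dists)
ba = o.agreement(areas_auto, areas_true)
print(f"lumen:  sensitivity {100*tp/(tp+fn):.2f}%  specificity {100*tn/(tn+fp):.2f}%")
print(f"lumen:  contour distance Q1/median/Q3 = {q1:.1f}/{med:.1f}/{q3:.1f} um")
print(f"lumen:  area bias {ba.bias:+.3f} mm^2, 95% LoA [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}]")
print(f"struts: sensitivity {100*rtp/(rtp+rfn):.1f}%  precision {100*rtp/(rtp+rfp):.1f}%  ({rtp} matched)")

model = o.fit_strut_count_model(truth.strut_counts)
report = o.assess_pullback([len(s.struts) for s in segs], model,
                           threshold_frames=None)
print(report.summary())
```

prints

```
lumen:  sensitivity 98.97%  specificity 99.97%
lumen:  contour distance Q1/median/Q3 = 4.9/9.5/13.7 um
lumen:  area bias -0.057 mm^2, 95% LoA [-0.074, -0.039]
struts: sensitivity 100.0%  precision 100.0%  (80 matched)
pullback quality: GOOD
frames considered: 10
poor frames: 1 (threshold: > 2)
per-frame cutoff: count < 5.95 struts
```

Reading the numbers: the traced contour sits within one pixel (15 um) of
the true boundary for most A-scans (median distance 9.5 um), which drives
lumen sensitivity ~99% / specificity ~100% and a small negative area bias
(the first gradient crossing fires one sample inside the wall). On a clean
phantom every one of the 80 rendered struts is recovered with no false
positives; one frame drew an unusually low strut count from the Gaussian
(below the 5% cutoff of 5.95) and is flagged poor, but the pullback stays
*good* because only 1 of 10 frames is poor, under the 20% threshold.

On degraded phantoms ("open-box" struts whose bright rim has a 30-50% gap,
plus blood speckle) strut sensitivity falls — the flood-fill core detector
cannot see an open box — while precision stays high, and the quality
classifier flags such pullbacks as *poor*.

## Command line

```sh
octseg phantom out/phantom --frames 50 --seed 1          # synthetic pullback + truth
octseg segment out/phantom out/run --phantom-config      # segment a pullback
octseg validate out/run out/phantom/ground_truth --out val.json
octseg quality --counts counts.csv --reference ref.csv   # pullback quality
octseg export-cloud out/run                              # 3D point cloud (CSV + PLY)
```

`segment` accepts a directory of numbered PNG frames (with optional
`metadata.json`) or a multi-frame TIFF, and writes contours (CSV), strut
centroids (CSV), lumen/strut masks (PNG), the 3D point cloud (CSV + ASCII
PLY), and the run configuration (YAML).

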