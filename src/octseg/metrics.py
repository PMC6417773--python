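"""Validation metrics for lumen and strut segmentations.

Lumen segmentations are compared pixel-wise (each pixel is a sample) via
sensitivity TP/(TP+FN), specificity TN/(TN+FP) and precision TP/(TP+FP).
Strut segmentations are compared region-wise: an automatic region is a true
positive if it overlaps a reference region by at least one pixel.  Matched
strut pairs yield centroid distances (total, and the radial component about
the lumen centre), contours yield per-A-scan radial distances, and lumen
areas are compared with linear regression and Bland-Altman analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import pearsonr
from shapely.geometry import Polygon

from .core import LumenContour, StrutRegion, StrutRegionSet

__all__ = [
    "ConfusionCounts",
    "SimilarityIndexes",
    "AgreementSummary",
    "pixel_confusion",
    "similarity_indexes",
    "region_match",
    "strut_distances",
    "contour_distance",
    "lumen_area",
    "agreement",
    "distance_quartiles",
]


@dataclass
class ConfusionCounts:
    """TP/FP/FN(/TN) counts; TN is undefined for region-wise comparison."""

    tp: int
    fp: int
    fn: int
    tn: Optional[int] = None

    def __post_init__(self) -> None:
        vals = [self.tp, self.fp, self.fn] + ([] if self.tn is None else [self.tn])
        if any(v < 0 for v in vals):
            raise ValueError("confusion counts must be non-negative")


@dataclass
class SimilarityIndexes:
    """Similarity indexes; ``None`` marks an undefined (0/0) value."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]


@dataclass
class AgreementSummary:
    """Bland-Altman bias and limits of agreement plus Pearson correlation."""

    bias: float
    loa_low: float
    loa_high: float
    r: Optional[float]
    p_value: Optional[float]

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


def pixel_confusion(auto_mask: np.ndarray,
                    reference_mask: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts between two binary masks."""
    a = np.asarray(auto_mask, dtype=bool)
    r = np.asarray(reference_mask, dtype=bool)
    if a.shape != r.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {r.shape}")
    tp = int(np.count_nonzero(a & r))
    fp = int(np.count_nonzero(a & ~r))
    fn = int(np.count_nonzero(~a & r))
    tn = int(a.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int, name: str) -> Optional[float]:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
        return None
    return num / den


def similarity_indexes(counts: ConfusionCounts) -> SimilarityIndexes:
    """Sensitivity, specificity and precision from confusion counts.

    A zero denominator yields ``None`` (flagged with a warning), never a
    silent 0.  Specificity is ``None`` when TN is undefined (region-wise).
    """
    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    if counts.tn is None:
        spec = None
    else:
        spec = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    prec = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    return SimilarityIndexes(sensitivity=sens, specificity=spec, precision=prec)


def _label_image(regions: StrutRegionSet, shape: tuple[int, int]) -> np.ndarray:
    lbl = np.zeros(shape, dtype=np.int32)
    for i, reg in enumerate(regions, start=1):
        lbl[reg.coords[:, 0], reg.coords[:, 1]] = i
    return lbl


def _common_shape(*sets: StrutRegionSet) -> tuple[int, int]:
    hi = [1, 1]
    for s in sets:
        for reg in s:
            hi[0] = max(hi[0], int(reg.coords[:, 0].max()) + 1)
            hi[1] = max(hi[1], int(reg.coords[:, 1].max()) + 1)
    return (hi[0], hi[1])


def region_match(auto: StrutRegionSet, reference: StrutRegionSet,
                 one_to_one: bool = False
                 ) -> tuple[ConfusionCounts, list[tuple[int, int]]]:
    """Region-wise confusion counts and matched (auto, reference) index pairs.

    Default semantics: an automatic region overlapping any reference region
    by >= 1 pixel is a TP, paired with the maximally overlapping reference
    region (two automatic regions may share one reference region); otherwise
    it is a FP.  A reference region with zero overlap against all automatic
    regions is a FN.  With ``one_to_one=True`` pairs are assigned greedily by
    descending overlap and each region is used at most once; leftovers count
    FP / FN.
    """
    shape = _common_shape(auto, reference)
    ref_lbl = _label_image(reference, shape)

    overlaps: dict[tuple[int, int], int] = {}
    for i, reg in enumerate(auto):
        labs, cnt = np.unique(ref_lbl[reg.coords[:, 0], reg.coords[:, 1]],
                              return_counts=True)
        for lab, n in zip(labs, cnt):
            if lab > 0:
                overlaps[(i, int(lab) - 1)] = int(n)

    pairs: list[tuple[int, int]] = []
    if one_to_one:
        used_auto: set[int] = set()
        used_ref: set[int] = set()
        for (i, j), _n in sorted(overlaps.items(),
                                 key=lambda kv: (-kv[1], kv[0])):
            if i not in used_auto and j not in used_ref:
                pairs.append((i, j))
                used_auto.add(i)
                used_ref.add(j)
        tp = len(pairs)
        fp = len(auto) - tp
        fn = len(reference) - tp
    else:
        matched_refs = {j for (_i, j) in overlaps}
        for i in range(len(auto)):
            cand = [(n, j) for (ai, j), n in overlaps.items() if ai == i]
            if cand:
                best = max(cand)  # max overlap, ties to larger ref index
                pairs.append((i, best[1]))
        tp = len(pairs)
        fp = len(auto) - tp
        fn = len(reference) - len(matched_refs)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=None), pairs


def strut_distances(matched_pairs: Sequence[tuple[StrutRegion, StrutRegion]],
                    lumen_center_rc: tuple[float, float],
                    pixel_size_um: float = 15.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Total and radial centroid distances (um) of matched strut pairs.

    Total: Euclidean distance between the two centroids.  Radial: absolute
    difference of the two centroid-to-lumen-centre distances.
    """
    if not matched_pairs:
        warnings.warn("no matched strut pairs: empty distance lists",
                      stacklevel=2)
        return np.empty(0), np.empty(0)
    r0, c0 = lumen_center_rc
    total, radial = [], []
    for auto_reg, ref_reg in matched_pairs:
        ca = np.array(auto_reg.centroid_rc)
        cr = np.array(ref_reg.centroid_rc)
        total.append(np.linalg.norm(ca - cr))
        da = np.hypot(ca[0] - r0, ca[1] - c0)
        dr = np.hypot(cr[0] - r0, cr[1] - c0)
        radial.append(abs(da - dr))
    return (np.asarray(total) * pixel_size_um,
            np.asarray(radial) * pixel_size_um)


def contour_distance(auto: LumenContour, reference: LumenContour,
                     pixel_size_um: float = 15.0) -> np.ndarray:
    """Per-A-scan |r_auto - r_ref| in micrometres.

    If the reference was sampled on a different theta grid it is resampled
    onto the automatic grid (with a warning).
    """
    ref_r = reference.radius_px
    if reference.n_theta != auto.n_theta:
        warnings.warn("contours sampled on different theta grids: "
                      "resampling reference", stacklevel=2)
        ref_r = np.interp(auto.thetas, reference.thetas, reference.radius_px,
                          period=2.0 * np.pi)
    return np.abs(auto.radius_px - ref_r) * auto.r_step_px * pixel_size_um


def lumen_area(contour: LumenContour | np.ndarray,
               pixel_size_um: float = 15.0) -> float:
    """Polygon (shoelace) area of a closed contour in mm^2.

    ``contour`` is a :class:`LumenContour` or an (N, 2) array of (row, col)
    vertices.  Self-intersecting polygons are rejected.
    """
    if isinstance(contour, LumenContour):
        pts = contour.cartesian_points(closed=False) * contour.r_step_px
    else:
        pts = np.asarray(contour, dtype=float)
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
    poly = Polygon(pts)
    if not poly.is_valid:
        raise ValueError("self-intersecting contour: area is ill-defined")
    y = pts[:, 0]
    x = pts[:, 1]
    area_px2 = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area_px2 * (pixel_size_um / 1000.0) ** 2)


def agreement(areas_a: Sequence[float],
              areas_b: Sequence[float]) -> AgreementSummary:
    """Bland-Altman bias / 95% limits of agreement and Pearson correlation.

    bias = mean(A - B); limits = bias +/- 1.96 * sd(A - B).  With zero
    variance in either series the correlation is flagged undefined.
    """
    a = np.asarray(list(areas_a), dtype=float)
    b = np.asarray(list(areas_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant series: correlation undefined", stacklevel=2)
        r, p = None, None
    else:
        rr = pearsonr(a, b)
        r, p = float(rr.statistic), float(rr.pvalue)
    return AgreementSummary(bias=bias, loa_low=bias - 1.96 * sd,
                            loa_high=bias + 1.96 * sd, r=r, p_value=p)


def distance_quartiles(distances: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, median, Q3) of a distance distribution."""
    q1, med, q3 = np.percentile(np.asarray(list(distances), dtype=float),
                                [25, 50, 75])
    return float(q1), float(med), float(q3)
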