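"""Per-pullback orchestration and 3D point-cloud export.

The per-frame flow is: artifact removal -> lumen-noise masking -> polar
resampling and lumen tracing -> strut segmentation (with rough-segmentation
centroids pooled over adjacent frames) -> optional strut-based lumen
correction -> optional per-frame quality label.  Rough centroids are
computed in a first pass over all frames and reference lines in a second,
so results do not depend on processing order; boundary frames use a
truncated window.  Frame-level failures are logged and skipped; the run
fails only if every frame fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import LumenContour, OctFrame, Pullback, StrutRegionSet
from .correction import correct_lumen
from .lumen import LumenConfig, segment_lumen
from .preprocess import PreprocessConfig, remove_artifacts
from .quality import QualityReport, StrutCountModel, assess_pullback
from .stent import StentConfig, rough_struts, segment_struts

__all__ = [
    "RunConfig",
    "FrameSegmentation",
    "run_pullback",
    "export_point_cloud",
    "write_point_cloud",
]

log = logging.getLogger("octseg")


@dataclass
class RunConfig:
    """All knobs of one segmentation run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    lumen: LumenConfig = field(default_factory=LumenConfig)
    stent: StentConfig = field(default_factory=StentConfig)
    correction: bool = True
    quality_quantile_level: float = 0.05
    quality_threshold_frames: Optional[int] = 10
    quality_threshold_fraction: Optional[float] = 0.20


@dataclass
class FrameSegmentation:
    """Segmentation products of one frame."""

    frame_index: int
    contour_raw: Optional[LumenContour] = None
    contour: Optional[LumenContour] = None
    struts: Optional[StrutRegionSet] = None
    rough: Optional[StrutRegionSet] = None
    quality_label: Optional[str] = None
    failed: bool = False
    error: Optional[str] = None


def run_pullback(pullback: Pullback, cfg: RunConfig,
                 model: Optional[StrutCountModel] = None
                 ) -> tuple[list[FrameSegmentation], Optional[QualityReport]]:
    """Segment every frame of a pullback.

    Returns one :class:`FrameSegmentation` per frame (failed frames are
    marked, not dropped) and, when a :class:`StrutCountModel` is supplied,
    the pullback :class:`QualityReport` computed over the non-failed frames.
    """
    segs: list[FrameSegmentation] = []
    cleaned: list[Optional[OctFrame]] = []

    # pass 1: artifacts, lumen, rough struts
    for frame in pullback:
        seg = FrameSegmentation(frame_index=frame.frame_index)
        try:
            clean = remove_artifacts(frame, cfg.preprocess)
            seg.contour_raw = segment_lumen(clean, cfg.preprocess, cfg.lumen)
            seg.rough = rough_struts(clean, cfg.stent)
            cleaned.append(clean)
        except Exception as exc:  # frame-level failure: log and continue
            log.warning("frame %d failed in pass 1: %s", frame.frame_index, exc)
            seg.failed = True
            seg.error = str(exc)
            cleaned.append(None)
        segs.append(seg)

    if all(s.failed for s in segs):
        raise RuntimeError("all frames failed; cannot segment pullback")

    # pass 2: reference lines from pooled rough centroids, struts, correction
    w = cfg.stent.adjacent_frames
    n = len(segs)
    for i, seg in enumerate(segs):
        if seg.failed:
            continue
        try:
            pooled = [s.rough.centroids_rc
                      for s in segs[max(0, i - w):min(n, i + w + 1)]
                      if s.rough is not None and len(s.rough)]
            centroids = (np.vstack(pooled) if pooled
                         else np.empty((0, 2)))
            seg.struts = segment_struts(cleaned[i], seg.contour_raw,
                                        centroids, cfg.stent)
            if cfg.correction and len(seg.struts):
                seg.contour = correct_lumen(seg.contour_raw, seg.struts,
                                            smoothing=cfg.lumen.smoothing)
            else:
                seg.contour = seg.contour_raw.copy(corrected=False)
            log.info("frame %d: %d struts, lumen radius %.1f px",
                     seg.frame_index, len(seg.struts),
                     float(seg.contour.radius_px.mean()))
        except Exception as exc:
            log.warning("frame %d failed in pass 2: %s", seg.frame_index, exc)
            seg.failed = True
            seg.error = str(exc)

    if all(s.failed for s in segs):
        raise RuntimeError("all frames failed; cannot segment pullback")

    report: Optional[QualityReport] = None
    if model is not None:
        ok = [s for s in segs if not s.failed]
        counts = [len(s.struts) for s in ok]
        report = assess_pullback(
            counts, model,
            threshold_frames=cfg.quality_threshold_frames,
            threshold_fraction=cfg.quality_threshold_fraction)
        for s, lab in zip(ok, report.frame_labels):
            s.quality_label = lab
    return segs, report


def export_point_cloud(segs: list[FrameSegmentation],
                       frame_spacing_um: float = 125.0,
                       pixel_size_um: float = 15.0) -> pd.DataFrame:
    """3D point cloud of lumen contours and strut centroids.

    Coordinates are micrometres about the polar centre; each frame sits at
    ``z = frame_index * frame_spacing_um``.  ``kind`` is ``lumen`` or
    ``strut``.
    """
    rows = []
    for seg in segs:
        if seg.failed or seg.contour is None:
            continue
        z = seg.frame_index * frame_spacing_um
        r0, c0 = seg.contour.center_rc
        pts = seg.contour.cartesian_points(closed=False)
        for y, x in pts:
            rows.append(((x - c0) * pixel_size_um, (y - r0) * pixel_size_um,
                         z, "lumen", seg.frame_index))
        if seg.struts is not None:
            for y, x in seg.struts.centroids_rc:
                rows.append(((x - c0) * pixel_size_um,
                             (y - r0) * pixel_size_um, z, "strut",
                             seg.frame_index))
    if not rows:
        raise ValueError("no successful frames to export")
    return pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "kind",
                                       "frame_index"])


def write_point_cloud(cloud: pd.DataFrame, csv_path=None,
                      ply_path=None) -> None:
    """Write the point cloud as labelled CSV and/or ASCII PLY."""
    if csv_path is not None:
        cloud.to_csv(csv_path, index=False)
    if ply_path is not None:
        with open(ply_path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n"
                     f"element vertex {len(cloud)}\n"
                     "property float x\nproperty float y\nproperty float z\n"
                     "property uchar red\nproperty uchar green\n"
                     "property uchar blue\nend_header\n")
            for _, row in cloud.iterrows():
                color = "255 0 0" if row.kind == "strut" else "0 0 255"
                fh.write(f"{row.x_um:.1f} {row.y_um:.1f} {row.z_um:.1f} "
                         f"{color}\n")
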