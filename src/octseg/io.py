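"""Reading and writing pullbacks, masks, contours, struts and configs.

Pullbacks are stored as numbered 8-bit PNG frames (or a multi-frame TIFF)
with a sidecar ``metadata.json`` carrying the physical scale.  Masks are 0/255
PNGs.  Contours and strut centroids are plain CSV.  The run configuration is
one YAML document mirroring the config dataclass field names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import LumenContour, OctFrame, Pullback, StrutRegionSet
from .lumen import LumenConfig
from .pipeline import FrameSegmentation, RunConfig
from .preprocess import PreprocessConfig
from .stent import StentConfig

__all__ = [
    "read_pullback",
    "write_pullback",
    "read_mask",
    "write_mask",
    "write_contours_csv",
    "write_struts_csv",
    "load_run_config",
    "save_run_config",
    "write_phantom",
]

_FRAME_EXTS = (".png", ".tif", ".tiff", ".bmp")


def _to_uint8(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:  # collapse RGB(A) to gray
        img = img[..., :3].mean(axis=-1)
    if img.dtype == np.uint8:
        return img
    img = img.astype(float)
    # linear rescale-on-read for higher bit depths
    if img.max() > 255:
        img = img * (255.0 / img.max())
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def read_pullback(path, pixel_size_um: float = 15.0,
                  frame_spacing_um: float = 125.0) -> Pullback:
    """Load a pullback from a frame directory or a multi-frame TIFF.

    A ``metadata.json`` next to the frames overrides the physical scale.
    """
    path = Path(path)
    if path.is_dir():
        meta = path / "metadata.json"
        if meta.exists():
            with open(meta) as fh:
                md = json.load(fh)
            pixel_size_um = md.get("pixel_size_um", pixel_size_um)
            frame_spacing_um = md.get("frame_spacing_um", frame_spacing_um)
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _FRAME_EXTS)
        if not files:
            raise FileNotFoundError(f"no frame images in {path}")
        stack = [_to_uint8(iio.imread(f)) for f in files]
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        stack = [_to_uint8(a) for a in arr]
    else:
        raise ValueError(f"unsupported pullback input: {path}")
    frames = [OctFrame(pixels=img, pixel_size_um=pixel_size_um, frame_index=i)
              for i, img in enumerate(stack)]
    return Pullback(frames=frames, frame_spacing_um=frame_spacing_um)


def write_pullback(pullback: Pullback, out_dir,
                   extra_metadata: Optional[dict] = None) -> Path:
    """Write numbered PNG frames plus ``metadata.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for frame in pullback:
        iio.imwrite(out / f"frame_{frame.frame_index:04d}.png", frame.pixels)
    md = {"pixel_size_um": pullback.pixel_size_um,
          "frame_spacing_um": pullback.frame_spacing_um,
          "n_frames": len(pullback)}
    if extra_metadata:
        md.update(extra_metadata)
    with open(out / "metadata.json", "w") as fh:
        json.dump(md, fh, indent=2, default=str)
    return out


def read_mask(path) -> np.ndarray:
    return _to_uint8(iio.imread(Path(path))) > 127


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def write_contours_csv(segs: list[FrameSegmentation], path) -> None:
    """One row per (frame, A-scan): theta, radius and Cartesian position."""
    rows = []
    for seg in segs:
        if seg.failed or seg.contour is None:
            continue
        cnt = seg.contour
        pts = cnt.cartesian_points(closed=False)
        for k, (th, r) in enumerate(zip(cnt.thetas, cnt.radius_px)):
            rows.append((seg.frame_index, k, th, r, pts[k, 1], pts[k, 0],
                         cnt.corrected))
    pd.DataFrame(rows, columns=["frame", "a_scan_index", "theta_rad",
                                "radius_px", "x_px", "y_px",
                                "corrected"]).to_csv(path, index=False)


def write_struts_csv(strut_sets: list[StrutRegionSet], path) -> None:
    rows = []
    for sset in strut_sets:
        for rid, reg in enumerate(sset):
            r, c = reg.centroid_rc
            rows.append((sset.frame_index, rid, c, r, reg.area_px))
    pd.DataFrame(rows, columns=["frame", "region_id", "centroid_x_px",
                                "centroid_y_px",
                                "area_px"]).to_csv(path, index=False)


# --- configuration -------------------------------------------------------

def save_run_config(cfg: RunConfig, path) -> None:
    doc = dataclasses.asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _tupled(d: dict, cls) -> dict:
    """YAML round-trips tuples as lists; restore tuple-typed fields."""
    out = dict(d)
    for f in dataclasses.fields(cls):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(out[f.name])
    return out


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig(
        preprocess=PreprocessConfig(**_tupled(doc.get("preprocess", {}),
                                              PreprocessConfig)),
        lumen=LumenConfig(**doc.get("lumen", {})),
        stent=StentConfig(**doc.get("stent", {})),
        correction=doc.get("correction", True),
        quality_quantile_level=doc.get("quality_quantile_level", 0.05),
        quality_threshold_frames=doc.get("quality_threshold_frames", 10),
        quality_threshold_fraction=doc.get("quality_threshold_fraction", 0.20),
    )


def write_phantom(out_dir, pullback: Pullback, truth,
                  spec=None) -> Path:
    """Write a phantom pullback plus its ground truth.

    Frames as numbered PNGs with metadata, true lumen masks as 0/255 PNGs,
    and true strut centroids as one CSV (frame, x_px, y_px, area_px).
    """
    out = Path(out_dir)
    extra = {}
    if spec is not None:
        extra["phantom_spec"] = dataclasses.asdict(spec)
    write_pullback(pullback, out, extra_metadata=extra)
    gt = out / "ground_truth"
    gt.mkdir(exist_ok=True)
    rows = []
    for ft in truth:
        write_mask(ft.lumen_mask, gt / f"lumen_{ft.frame_index:04d}.png")
        for reg in ft.strut_regions:
            r, c = reg.centroid_rc
            rows.append((ft.frame_index, c, r, reg.area_px))
    pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "area_px"]).to_csv(
        gt / "strut_centroids.csv", index=False)
    return out
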