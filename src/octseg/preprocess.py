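"""Frame pre-processing: artifact removal and the intra-lumen noise mask.

Two artifacts of the acquisition system are blanked before any segmentation:
the calibration bar drawn by the visualization console and the imaging
catheter itself.  Before lumen segmentation only, residual blood speckle
inside the lumen is suppressed by multiplying the frame with a binary mask
built from (1) intensity thresholding at a quantile of the frame's intensity
distribution, (2) morphological opening, and (3) small-component removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, opening

from .core import OctFrame

__all__ = [
    "PreprocessConfig",
    "remove_artifacts",
    "lumen_noise_mask",
    "apply_mask",
    "intensity_threshold",
]


@dataclass
class PreprocessConfig:
    """Parameters of artifact removal and lumen-noise masking.

    Attributes
    ----------
    intensity_quantile : float
        Quantile of the pixel intensity distribution used as threshold.
        Computed over *all* pixels of the artifact-removed frame (zeros
        included) with the inclusive linear-interpolation definition.
    opening_radius_px : int
        Radius of the disk structuring element for the morphological opening.
    min_area_px : int
        Connected components (8-connectivity) smaller than this survive
        neither step of area thresholding.
    catheter_center_rc : tuple or None
        (row, col) centre of the catheter exclusion disk; ``None`` means the
        image centre.
    catheter_radius_px : float
        Radius of the catheter exclusion disk; 0 disables it.
    calibration_bar_rows, calibration_bar_cols : tuple or None
        Half-open (start, stop) ranges of the calibration-bar rectangle to
        blank.  A ``None`` range spans the whole axis; both ``None`` disables
        bar removal.
    """

    intensity_quantile: float = 0.85
    opening_radius_px: int = 2
    min_area_px: int = 50
    catheter_center_rc: Optional[tuple[float, float]] = None
    catheter_radius_px: float = 0.0
    calibration_bar_rows: Optional[tuple[int, int]] = None
    calibration_bar_cols: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.intensity_quantile < 1.0:
            raise ValueError("intensity_quantile must lie in (0, 1)")
        if self.opening_radius_px < 0 or self.min_area_px < 0:
            raise ValueError("radii and areas must be non-negative")
        if self.catheter_radius_px < 0:
            raise ValueError("catheter_radius_px must be non-negative")

    def catheter_center(self, shape: tuple[int, int]) -> tuple[float, float]:
        if self.catheter_center_rc is not None:
            return tuple(self.catheter_center_rc)  # type: ignore[return-value]
        return ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)


def _bar_slices(cfg: PreprocessConfig,
                shape: tuple[int, int]) -> Optional[tuple[slice, slice]]:
    if cfg.calibration_bar_rows is None and cfg.calibration_bar_cols is None:
        return None
    rows = cfg.calibration_bar_rows or (0, shape[0])
    cols = cfg.calibration_bar_cols or (0, shape[1])
    for (lo, hi), n, name in ((rows, shape[0], "rows"), (cols, shape[1], "cols")):
        if lo < 0 or hi > n or lo >= hi:
            raise ValueError(
                f"calibration bar {name} ({lo}, {hi}) outside frame of {n} {name}")
    return slice(*rows), slice(*cols)


def remove_artifacts(frame: OctFrame, cfg: PreprocessConfig) -> OctFrame:
    """Blank the calibration bar and the catheter disk.

    Pixels inside the catheter disk and the calibration-bar rectangle are set
    to 0; every other pixel is unchanged.
    """
    h, w = frame.shape
    out = frame.pixels.copy()

    bar = _bar_slices(cfg, frame.shape)
    if bar is not None:
        out[bar] = 0

    if cfg.catheter_radius_px > 0:
        r0, c0 = cfg.catheter_center(frame.shape)
        rad = cfg.catheter_radius_px
        if (r0 - rad < -0.5 or r0 + rad > h - 0.5
                or c0 - rad < -0.5 or c0 + rad > w - 0.5):
            raise ValueError(
                f"catheter disk (center=({r0}, {c0}), radius={rad}) "
                f"exceeds frame bounds {frame.shape}")
        rr, cc = np.ogrid[:h, :w]
        out[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2] = 0

    return frame.with_pixels(out)


def intensity_threshold(pixels: np.ndarray, quantile: float) -> float:
    """Quantile intensity threshold over all pixels (linear interpolation)."""
    return float(np.quantile(np.asarray(pixels, dtype=float), quantile))


def lumen_noise_mask(frame: OctFrame, cfg: PreprocessConfig) -> np.ndarray:
    """Binary mask keeping the vessel wall and rejecting intra-lumen speckle.

    Pipeline: intensity thresholding at ``cfg.intensity_quantile`` of the
    frame's distribution, morphological opening with a disk of
    ``cfg.opening_radius_px``, then removal of 8-connected components smaller
    than ``cfg.min_area_px``.
    """
    px = frame.pixels
    if px.size == 0 or px.min() == px.max():
        warnings.warn("constant-intensity frame: quantile threshold is "
                      "degenerate, returning an empty mask", stacklevel=2)
        return np.zeros(frame.shape, dtype=bool)

    thr = intensity_threshold(px, cfg.intensity_quantile)
    mask = px >= thr
    if cfg.opening_radius_px > 0:
        mask = opening(mask, disk(cfg.opening_radius_px))
    if cfg.min_area_px > 1:
        mask = _drop_small_components(mask, cfg.min_area_px)
    return mask


def _drop_small_components(mask: np.ndarray, min_area_px: int) -> np.ndarray:
    """Remove 8-connected components with area < min_area_px."""
    lbl, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = np.bincount(lbl.ravel())
    keep = sizes >= min_area_px
    keep[0] = False
    return keep[lbl]


def apply_mask(frame: OctFrame, mask: np.ndarray) -> OctFrame:
    """Element-wise product of the frame with a binary mask."""
    mask = np.asarray(mask)
    if mask.shape != frame.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {frame.shape}")
    return frame.with_pixels(frame.pixels * mask.astype(np.uint8))
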