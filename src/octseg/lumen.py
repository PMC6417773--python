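"""Lumen contour detection.

The noise-masked frame is resampled into polar coordinates (r, theta) about
the catheter centre so that every row of the polar image is one A-scan.  A
Sobel filter along the radial axis marks intensity edges; per A-scan the
first sufficiently strong dark-to-bright edge is taken as the lumen boundary.
A periodic smoothing spline over theta fills A-scans where no edge was found
(guide-wire shadows, dropouts) and yields the closed Cartesian contour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import splev, splrep

from .core import LumenContour, OctFrame, PolarImage
from .preprocess import PreprocessConfig, apply_mask, lumen_noise_mask

__all__ = [
    "LumenConfig",
    "cartesian_to_polar",
    "polar_to_cartesian",
    "trace_lumen",
    "interpolate_contour",
    "periodic_spline",
    "segment_lumen",
]


@dataclass
class LumenConfig:
    """Parameters of polar resampling and edge tracing.

    ``n_theta`` A-scans cover [0, 2*pi); ``n_r`` defaults to half the image
    diagonal at ``r_step_px`` = 1 so polar sampling is at least as fine as the
    Cartesian grid.  The Sobel response of each A-scan is thresholded at
    ``gradient_threshold`` times its own maximum; only positive
    (dark-to-bright) radial gradients qualify as the first lumen edge.
    """

    n_theta: int = 360
    n_r: Optional[int] = None
    r_step_px: float = 1.0
    gradient_threshold: float = 0.3
    min_response: float = 1e-6
    smoothing: float = 0.0
    max_gap_deg: float = 120.0

    def __post_init__(self) -> None:
        if self.n_theta < 4 or (self.n_r is not None and self.n_r < 4):
            raise ValueError("n_theta and n_r must both be >= 4")
        if not 0.0 < self.gradient_threshold <= 1.0:
            raise ValueError("gradient_threshold must lie in (0, 1]")
        if self.r_step_px <= 0:
            raise ValueError("r_step_px must be positive")


def _default_center(shape: tuple[int, int]) -> tuple[float, float]:
    return ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)


def cartesian_to_polar(frame: OctFrame | np.ndarray,
                       center_rc: Optional[tuple[float, float]] = None,
                       n_theta: int = 360,
                       n_r: Optional[int] = None,
                       r_step_px: float = 1.0) -> PolarImage:
    """Resample a frame on an (theta, r) grid by bilinear interpolation.

    Samples falling outside the frame are 0.
    """
    img = frame.pixels if isinstance(frame, OctFrame) else np.asarray(frame)
    img = img.astype(float)
    if n_theta < 4 or (n_r is not None and n_r < 4):
        raise ValueError("n_theta and n_r must both be >= 4")
    h, w = img.shape
    if center_rc is None:
        center_rc = _default_center(img.shape)
    r0, c0 = center_rc
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError(f"center {center_rc} lies outside frame {img.shape}")
    if n_r is None:
        n_r = int(np.ceil(0.5 * np.hypot(h, w) / r_step_px))
    th = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    r = np.arange(n_r) * r_step_px
    rows = r0 + np.outer(np.sin(th), r)
    cols = c0 + np.outer(np.cos(th), r)
    data = ndi.map_coordinates(img, [rows, cols], order=1, mode="constant",
                               cval=0.0)
    return PolarImage(data=data, center_rc=(r0, c0), r_step_px=r_step_px)


def polar_to_cartesian(polar: PolarImage, shape: tuple[int, int]) -> np.ndarray:
    """Inverse resampling of a polar image back onto a Cartesian grid.

    Pixels outside the sampled annulus are 0.  Used for round-trip checks and
    visualization; the segmentation itself converts contours analytically.
    """
    r0, c0 = polar.center_rc
    rr, cc = np.indices(shape)
    dr = rr - r0
    dc = cc - c0
    rad_idx = np.hypot(dr, dc) / polar.r_step_px
    th_idx = (np.arctan2(dr, dc) % (2.0 * np.pi)) / (2.0 * np.pi / polar.n_theta)
    # pad one wrapped row so interpolation across theta = 2*pi is seamless
    data = np.vstack([polar.data, polar.data[:1]])
    return ndi.map_coordinates(data, [th_idx, rad_idx], order=1,
                               mode="constant", cval=0.0)


def trace_lumen(polar: PolarImage,
                gradient_threshold: float = 0.3,
                min_response: float = 1e-6) -> np.ndarray:
    """First dark-to-bright edge per A-scan.

    Returns one radius (in pixels) per A-scan; A-scans whose strongest
    positive radial Sobel response does not exceed ``min_response`` are
    returned as NaN (missing).  Raises if every A-scan is missing.

    The derivative kernel [-1, 0, 1] is applied along r only, per A-scan,
    without cross-A-scan smoothing: a fully shadowed A-scan must stay
    missing instead of borrowing its neighbours' edges.
    """
    data = polar.data
    resp = np.zeros_like(data)
    resp[:, 1:-1] = data[:, 2:] - data[:, :-2]
    np.clip(resp, 0.0, None, out=resp)
    peak = resp.max(axis=1)
    valid = peak > min_response
    if not valid.any():
        raise ValueError("no lumen found: no A-scan has an edge response")
    thr = gradient_threshold * peak
    above = resp >= thr[:, None]
    first = above.argmax(axis=1).astype(float)
    radii = first * polar.r_step_px
    radii[~valid] = np.nan
    return radii


def periodic_spline(theta: np.ndarray, values: np.ndarray,
                    theta_out: np.ndarray, smoothing: float = 0.0,
                    k: int = 3) -> np.ndarray:
    """Fit a periodic smoothing spline over [0, 2*pi) and evaluate it.

    ``theta`` must be sorted and duplicate-free within one period.
    """
    x = np.concatenate([theta, [theta[0] + 2.0 * np.pi]])
    y = np.concatenate([values, [values[0]]])
    k = min(k, len(theta) - 1)
    tck = splrep(x, y, per=1, s=smoothing, k=k)
    return np.asarray(splev(theta_out % (2.0 * np.pi), tck), dtype=float)


def interpolate_contour(raw_radii: np.ndarray,
                        center_rc: tuple[float, float],
                        r_step_px: float = 1.0,
                        smoothing: float = 0.0,
                        max_gap_deg: float = 120.0) -> LumenContour:
    """Periodic spline through the traced radii, filling missing A-scans.

    Requires at least 8 valid A-scans.  Gaps wider than ``max_gap_deg``
    degrees trigger a warning (the spline still fills them).
    """
    raw = np.asarray(raw_radii, dtype=float)
    n_theta = raw.size
    th = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    valid = np.isfinite(raw) & (raw > 0)
    n_valid = int(valid.sum())
    if n_valid < 8:
        raise ValueError(f"only {n_valid} valid A-scans; need at least 8")

    th_v = th[valid]
    gaps = np.diff(np.concatenate([th_v, [th_v[0] + 2.0 * np.pi]]))
    if np.degrees(gaps.max()) > max_gap_deg:
        warnings.warn(
            f"lumen trace has a {np.degrees(gaps.max()):.0f} deg gap; "
            "contour interpolated across it", stacklevel=2)

    radii = periodic_spline(th_v, raw[valid], th, smoothing=smoothing)
    radii = np.clip(radii, 1e-3, None)
    return LumenContour(radius_px=radii, center_rc=center_rc,
                        r_step_px=r_step_px, corrected=False)


def segment_lumen(frame: OctFrame, pre_cfg: PreprocessConfig,
                  cfg: LumenConfig) -> LumenContour:
    """Noise-mask a pre-processed frame and trace its lumen contour."""
    masked = apply_mask(frame, lumen_noise_mask(frame, pre_cfg))
    center = pre_cfg.catheter_center(frame.shape)
    polar = cartesian_to_polar(masked, center_rc=center, n_theta=cfg.n_theta,
                               n_r=cfg.n_r, r_step_px=cfg.r_step_px)
    raw = trace_lumen(polar, gradient_threshold=cfg.gradient_threshold,
                      min_response=cfg.min_response)
    return interpolate_contour(raw, center_rc=center, r_step_px=cfg.r_step_px,
                               smoothing=cfg.smoothing,
                               max_gap_deg=cfg.max_gap_deg)
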