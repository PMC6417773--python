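"""Shared data containers for OCT pullback segmentation.

Conventions used throughout the package:

* Images are 8-bit grayscale arrays indexed ``[row, col]``.
* Polar images are indexed ``[theta_index, r_index]``; the angle of A-scan
  ``k`` is ``theta_k = 2*pi*k / n_theta`` measured from the +x (column) axis
  with y (row) increasing downwards, so ``row = r*sin(theta)``,
  ``col = r*cos(theta)`` about the transform centre.
* Physical scale is carried as micrometres per pixel (in-plane) and
  micrometres between consecutive frames (longitudinal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from skimage.draw import polygon as draw_polygon

__all__ = [
    "OctFrame",
    "Pullback",
    "PolarImage",
    "LumenContour",
    "StrutRegion",
    "StrutRegionSet",
]


@dataclass
class OctFrame:
    """One cross-sectional OCT B-scan.

    Parameters
    ----------
    pixels : ndarray
        2D 8-bit grayscale image (values 0-255).
    pixel_size_um : float
        In-plane resolution in micrometres per pixel.
    frame_index : int
        Position of the frame within its pullback.
    """

    pixels: np.ndarray
    pixel_size_um: float = 15.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"frame pixels must be 2D, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.size and (px.min() < 0 or px.max() > 255):
                raise ValueError("frame intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "OctFrame":
        """Return a copy of this frame carrying new pixel data."""
        return OctFrame(pixels=pixels, pixel_size_um=self.pixel_size_um,
                        frame_index=self.frame_index)


@dataclass
class Pullback:
    """Ordered stack of frames acquired during catheter withdrawal."""

    frames: list[OctFrame]
    frame_spacing_um: float = 125.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a pullback needs at least one frame")
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError(f"frames have mixed dimensions: {sorted(shapes)}")
        if self.frame_spacing_um <= 0:
            raise ValueError("frame_spacing_um must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[OctFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> OctFrame:
        return self.frames[i]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def pixel_size_um(self) -> float:
        return self.frames[0].pixel_size_um


@dataclass
class PolarImage:
    """A frame resampled on an (theta, r) grid about a fixed centre.

    ``data[k, j]`` is the intensity at angle ``2*pi*k/n_theta`` and radius
    ``j * r_step_px`` pixels from ``center_rc``.
    """

    data: np.ndarray
    center_rc: tuple[float, float]
    r_step_px: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("polar data must be 2D (n_theta, n_r)")
        if self.r_step_px <= 0:
            raise ValueError("r_step_px must be positive")

    @property
    def n_theta(self) -> int:
        return self.data.shape[0]

    @property
    def n_r(self) -> int:
        return self.data.shape[1]

    @property
    def thetas(self) -> np.ndarray:
        return np.arange(self.n_theta) * (2.0 * np.pi / self.n_theta)

    @property
    def radii_px(self) -> np.ndarray:
        return np.arange(self.n_r) * self.r_step_px


@dataclass
class LumenContour:
    """Closed lumen contour: one radius per A-scan about a fixed centre."""

    radius_px: np.ndarray
    center_rc: tuple[float, float]
    r_step_px: float = 1.0
    corrected: bool = False

    def __post_init__(self) -> None:
        r = np.asarray(self.radius_px, dtype=float)
        if r.ndim != 1 or r.size < 4:
            raise ValueError("contour needs a 1D radius array (>= 4 A-scans)")
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ValueError("contour radii must be finite and positive")
        self.radius_px = r

    @property
    def n_theta(self) -> int:
        return self.radius_px.size

    @property
    def thetas(self) -> np.ndarray:
        return np.arange(self.n_theta) * (2.0 * np.pi / self.n_theta)

    def cartesian_points(self, closed: bool = True) -> np.ndarray:
        """Contour vertices as ``(row, col)`` pairs; closed repeats the first."""
        th = self.thetas
        r0, c0 = self.center_rc
        rows = r0 + self.radius_px * np.sin(th)
        cols = c0 + self.radius_px * np.cos(th)
        pts = np.column_stack([rows, cols])
        if closed:
            pts = np.vstack([pts, pts[:1]])
        return pts

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Filled boolean lumen mask of the given image shape."""
        pts = self.cartesian_points(closed=False)
        rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask

    def copy(self, **changes) -> "LumenContour":
        out = replace(self, **changes)
        out.radius_px = self.radius_px.copy() if "radius_px" not in changes else out.radius_px
        return out


@dataclass
class StrutRegion:
    """Connected pixel region accepted as one scaffold strut cross-section."""

    coords: np.ndarray  # (N, 2) int array of (row, col)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] == 0:
            raise ValueError("strut coords must be a non-empty (N, 2) array")
        self.coords = c.astype(np.intp)

    @property
    def area_px(self) -> int:
        return int(self.coords.shape[0])

    @property
    def centroid_rc(self) -> tuple[float, float]:
        m = self.coords.mean(axis=0)
        return float(m[0]), float(m[1])


@dataclass
class StrutRegionSet:
    """Strut regions of one frame plus provenance (``rough`` vs ``final``)."""

    frame_index: int
    regions: list[StrutRegion] = field(default_factory=list)
    provenance: str = "final"

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[StrutRegion]:
        return iter(self.regions)

    @property
    def centroids_rc(self) -> np.ndarray:
        if not self.regions:
            return np.empty((0, 2), dtype=float)
        return np.array([r.centroid_rc for r in self.regions], dtype=float)

    @property
    def areas_px(self) -> np.ndarray:
        return np.array([r.area_px for r in self.regions], dtype=int)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        for reg in self.regions:
            mask[reg.coords[:, 0], reg.coords[:, 1]] = True
        return mask


def regions_from_label_image(lbl: np.ndarray, frame_index: int,
                             provenance: str = "final") -> StrutRegionSet:
    """Build a :class:`StrutRegionSet` from a labelled integer image."""
    from skimage.measure import regionprops

    regions = [StrutRegion(coords=p.coords) for p in regionprops(lbl)]
    return StrutRegionSet(frame_index=frame_index, regions=regions,
                          provenance=provenance)
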