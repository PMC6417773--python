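"""Synthetic OCT pullback phantom with exact ground truth.

The phantom emulates the image features the segmentation exploits, not OCT
physics: a dark lumen bounded by a bright vessel wall (with a dimmer
deep-tissue band beyond it), box-shaped scaffold struts rendered as a dark
rectangular core inside a bright rim, optional "open-box" rim gaps on the
adluminal side, bright blood-residual speckle inside the lumen, a catheter
disk at the image centre, and a calibration bar at the image border.

Struts are placed with their abluminal face on the lumen boundary (slightly
penetrating the wall so no spurious enclosed gaps form between rim and
wall), i.e. the strut body is adluminal, as for well-apposed baseline
scaffolds.  Their angular positions are sampled without replacement from a
uniform slot grid with a minimum angular separation, so rendered regions
never merge and region-wise matching stays unambiguous.

Everything is deterministic given the spec: the per-frame RNG is derived
from ``(seed, frame_index)``, and the longitudinal lumen profile (a
low-order cosine modulation, smooth along the pullback) does not depend on
the seed at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .core import OctFrame, Pullback, StrutRegion, StrutRegionSet
from .preprocess import PreprocessConfig

__all__ = [
    "PhantomSpec",
    "FrameTruth",
    "PullbackTruth",
    "generate_frame",
    "generate_pullback",
    "preprocess_config_for",
    "run_config_for",
]

N_THETA_TRUTH = 360  # ground-truth A-scan grid, matches the lumen default


@dataclass
class PhantomSpec:
    """Parameters of the synthetic pullback.

    Geometry is in pixels; intensities are 8-bit levels.  ``strut_size_px``
    is (radial, tangential) extent of the full box including the rim.
    """

    image_size_px: int = 512
    pixel_size_um: float = 15.0
    frame_spacing_um: float = 125.0
    n_frames: int = 50
    lumen_radius_px: float = 100.0
    lumen_eccentricity: float = 0.1
    wall_intensity: int = 200
    wall_thickness_px: float = 80.0
    deep_intensity: int = 60
    strut_count_mean: float = 9.0
    strut_count_sd: float = 1.5
    strut_size_px: tuple[int, int] = (14, 20)
    rim_thickness_px: float = 2.0
    rim_intensity: int = 230
    core_intensity: int = 0
    strut_penetration_px: float = 2.0
    open_box_fraction: float = 0.0
    gap_fraction_range: tuple[float, float] = (0.3, 0.5)
    blood_noise_density: float = 0.0
    speckle_intensity: int = 220
    catheter_radius_px: float = 12.0
    catheter_intensity: int = 160
    calibration_bar_px: int = 4
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # --- derived geometry -------------------------------------------------
    def base_radius(self, frame_index: int) -> float:
        """Longitudinal lumen profile: seed-independent cosine modulation."""
        n = max(self.n_frames, 1)
        return self.lumen_radius_px * (1.0 + 0.06 * np.cos(
            2.0 * np.pi * frame_index / n))

    def radius_at(self, theta, frame_index: int):
        """True lumen radius at angle(s) ``theta`` of one frame."""
        phase = 0.1 * frame_index
        return self.base_radius(frame_index) * (
            1.0 + 0.5 * self.lumen_eccentricity * np.cos(2.0 * (theta - phase)))

    def _min_separation_rad(self) -> float:
        r_min = self.lumen_radius_px * 0.94 * (1 - 0.5 * self.lumen_eccentricity)
        return (1.4 * self.strut_size_px[1] + 4.0) / r_min

    def n_slots(self) -> int:
        return int(2.0 * np.pi / self._min_separation_rad())

    def validate(self) -> None:
        for name in ("wall_intensity", "deep_intensity", "rim_intensity",
                     "core_intensity", "speckle_intensity",
                     "catheter_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")
        for name in ("open_box_fraction", "blood_noise_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_frames < 1 or self.image_size_px < 32:
            raise ValueError("need n_frames >= 1 and image_size_px >= 32")
        r_max = self.lumen_radius_px * 1.06 * (1 + 0.5 * self.lumen_eccentricity)
        if r_max + max(self.strut_size_px) + 2 >= self.image_size_px / 2:
            raise ValueError(
                "geometric infeasibility: lumen radius plus strut extent "
                f"({r_max:.0f} + {max(self.strut_size_px)} px) does not fit "
                f"inside half the {self.image_size_px} px image")
        if self.catheter_radius_px >= self.lumen_radius_px * 0.9:
            raise ValueError("catheter disk does not fit inside the lumen")
        if self.strut_count_mean + 3 * self.strut_count_sd > self.n_slots():
            raise ValueError(
                "geometric infeasibility: the requested strut count "
                f"(mean {self.strut_count_mean} + 3 sd) exceeds the "
                f"{self.n_slots()} angular slots that keep struts separated")


@dataclass
class FrameTruth:
    """Exact per-frame ground truth matching the rendered pixels."""

    frame_index: int
    lumen_mask: np.ndarray
    lumen_radius_px: np.ndarray          # one radius per truth A-scan
    strut_regions: StrutRegionSet        # full box footprints
    speckle_mask: np.ndarray
    strut_footprint: np.ndarray

    @property
    def strut_count(self) -> int:
        return len(self.strut_regions)

    @property
    def strut_centroids_rc(self) -> np.ndarray:
        return self.strut_regions.centroids_rc


@dataclass
class PullbackTruth:
    """Ground truth for a whole pullback."""

    frames: list[FrameTruth] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> FrameTruth:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def strut_counts(self) -> np.ndarray:
        return np.array([f.strut_count for f in self.frames], dtype=int)


def _frame_rng(spec: PhantomSpec, frame_index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, frame_index])


def generate_frame(spec: PhantomSpec, frame_index: int,
                   rng: Optional[np.random.Generator] = None
                   ) -> tuple[OctFrame, FrameTruth]:
    """Render one frame and its ground truth.

    Deterministic: the default RNG is derived from ``(spec.seed,
    frame_index)``, so standalone frames match the ones inside
    :func:`generate_pullback`.
    """
    if frame_index >= spec.n_frames or frame_index < 0:
        raise ValueError(f"frame_index {frame_index} outside pullback of "
                         f"{spec.n_frames} frames")
    if rng is None:
        rng = _frame_rng(spec, frame_index)

    s = spec.image_size_px
    c = (s - 1) / 2.0
    rows, cols = np.indices((s, s))
    dy = rows - c
    dx = cols - c
    rad = np.hypot(dy, dx)
    ang = np.arctan2(dy, dx) % (2.0 * np.pi)
    r_wall = spec.radius_at(ang, frame_index)

    img = np.zeros((s, s), dtype=np.uint8)
    img[rad >= r_wall] = spec.wall_intensity
    img[rad >= r_wall + spec.wall_thickness_px] = spec.deep_intensity
    lumen_mask = rad < r_wall

    # --- struts -----------------------------------------------------------
    count = int(round(rng.normal(spec.strut_count_mean, spec.strut_count_sd)))
    count = max(0, min(count, spec.n_slots()))
    n_slots = spec.n_slots()
    slot_angles = ((np.arange(n_slots) + rng.uniform()) *
                   (2.0 * np.pi / n_slots))
    chosen = rng.choice(n_slots, size=count, replace=False)

    strut_footprint = np.zeros((s, s), dtype=bool)
    regions: list[StrutRegion] = []
    h, w = spec.strut_size_px
    rim_t = spec.rim_thickness_px
    for alpha in slot_angles[np.sort(chosen)]:
        r_a = float(spec.radius_at(alpha, frame_index))
        center_r = r_a + spec.strut_penetration_px - h / 2.0
        cy = c + center_r * np.sin(alpha)
        cx = c + center_r * np.cos(alpha)
        half = int(np.ceil(np.hypot(h, w) / 2.0)) + 2
        y0, y1 = max(0, int(cy) - half), min(s, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(s, int(cx) + half + 1)
        py, px = np.indices((y1 - y0, x1 - x0))
        gy = py + y0 - cy
        gx = px + x0 - cx
        du = gy * np.sin(alpha) + gx * np.cos(alpha)     # radial (outward +)
        dv = gy * np.cos(alpha) - gx * np.sin(alpha)     # tangential
        box = (np.abs(du) <= h / 2.0) & (np.abs(dv) <= w / 2.0)
        core = ((np.abs(du) <= h / 2.0 - rim_t)
                & (np.abs(dv) <= w / 2.0 - rim_t))
        rim = box & ~core

        patch = img[y0:y1, x0:x1]
        patch[rim] = spec.rim_intensity
        patch[core] = spec.core_intensity

        if spec.open_box_fraction > 0 and rng.uniform() < spec.open_box_fraction:
            gap_frac = rng.uniform(*spec.gap_fraction_range)
            ry, rx = np.nonzero(rim)
            lam = np.arctan2(dv[ry, rx], du[ry, rx])
            # contiguous arc centred on the adluminal (inward, lam ~ pi) side
            shifted = np.arctan2(np.sin(lam - np.pi), np.cos(lam - np.pi))
            m = int(round(gap_frac * ry.size))
            sel = np.argsort(np.abs(shifted))[:m]
            patch[ry[sel], rx[sel]] = 0

        box_coords = np.argwhere(box) + (y0, x0)
        regions.append(StrutRegion(coords=box_coords))
        strut_footprint[y0:y1, x0:x1] |= box

    # --- blood-residual speckle -------------------------------------------
    speckle = np.zeros((s, s), dtype=bool)
    if spec.blood_noise_density > 0:
        candidates = ((rad < r_wall - 3)
                      & (rad > spec.catheter_radius_px + 2)
                      & ~strut_footprint)
        seeds = (rng.random((s, s)) < spec.blood_noise_density) & candidates
        grow_r = seeds & (rng.random((s, s)) < 0.5)
        grow_d = seeds & (rng.random((s, s)) < 0.25)
        speckle = seeds.copy()
        speckle[:, 1:] |= grow_r[:, :-1]
        speckle[1:, :] |= grow_d[:-1, :]
        speckle &= candidates
        img[speckle] = spec.speckle_intensity

    # --- catheter and calibration bar -------------------------------------
    if spec.catheter_radius_px > 0:
        img[rad <= spec.catheter_radius_px] = spec.catheter_intensity
    if spec.calibration_bar_px > 0:
        img[s - spec.calibration_bar_px:, :] = 255

    if spec.blur_sigma > 0:
        img = np.clip(np.round(ndi.gaussian_filter(img.astype(float),
                                                   spec.blur_sigma)),
                      0, 255).astype(np.uint8)

    th = np.arange(N_THETA_TRUTH) * (2.0 * np.pi / N_THETA_TRUTH)
    truth = FrameTruth(
        frame_index=frame_index,
        lumen_mask=lumen_mask,
        lumen_radius_px=np.asarray(spec.radius_at(th, frame_index)),
        strut_regions=StrutRegionSet(frame_index=frame_index, regions=regions,
                                     provenance="truth"),
        speckle_mask=speckle,
        strut_footprint=strut_footprint,
    )
    frame = OctFrame(pixels=img, pixel_size_um=spec.pixel_size_um,
                     frame_index=frame_index)
    return frame, truth


def generate_pullback(spec: PhantomSpec) -> tuple[Pullback, PullbackTruth]:
    """Render the whole pullback with per-frame ground truth."""
    frames, truths = [], []
    for i in range(spec.n_frames):
        frame, truth = generate_frame(spec, i)
        frames.append(frame)
        truths.append(truth)
    return (Pullback(frames=frames, frame_spacing_um=spec.frame_spacing_um),
            PullbackTruth(frames=truths))


def preprocess_config_for(spec: PhantomSpec) -> PreprocessConfig:
    """Pre-processing config matching the phantom's rendered artifacts."""
    s = spec.image_size_px
    bar = ((s - spec.calibration_bar_px, s)
           if spec.calibration_bar_px > 0 else None)
    return PreprocessConfig(
        catheter_center_rc=None,
        catheter_radius_px=spec.catheter_radius_px + 2,
        calibration_bar_rows=bar,
    )


def run_config_for(spec: PhantomSpec, correction: bool = True):
    """Full pipeline config matching the phantom's artifacts."""
    from .pipeline import RunConfig  # local import avoids a cycle

    return RunConfig(preprocess=preprocess_config_for(spec),
                     correction=correction)
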