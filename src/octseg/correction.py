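"""Strut-based lumen correction.

At baseline, well-apposed scaffold struts sit on the lumen boundary, so the
first-edge tracer stops at a strut's inner rim (or at blood residue next to
it) and bites into the lumen.  The detected struts are used as a reference:
contour and strut masks are rendered in polar coordinates, the strut mask is
dilated with a 1x10 (radial x tangential) rectangle, and per A-scan the
outermost white pixel of the union becomes the corrected radius.  The
corrected radii are then re-fit with the same periodic spline used for the
original contour so pre- and post-correction contours stay comparable.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import LumenContour, StrutRegionSet
from .lumen import interpolate_contour

__all__ = ["correct_lumen"]


def correct_lumen(lumen: LumenContour, struts: StrutRegionSet,
                  tangential_halfwidth: int = 5,
                  radial_halfwidth: int = 0,
                  smoothing: float = 0.0) -> LumenContour:
    """Push the lumen contour to the outer edge of the detected struts.

    Per A-scan the corrected radius is the maximum of the traced radius and
    the largest radial coordinate of the (dilated) strut pixels falling on
    that A-scan.  The 1x10-pixel dilation of the strut mask is applied as
    +/-``tangential_halfwidth`` A-scan columns (with wrap-around) and
    +/-``radial_halfwidth`` radial samples.

    With an empty strut set the input contour is returned unchanged with
    ``corrected=False`` and a warning.
    """
    if len(struts) == 0:
        warnings.warn("no struts detected: lumen contour left uncorrected",
                      stacklevel=2)
        return lumen.copy(corrected=False)

    n_theta = lumen.n_theta
    d_theta = 2.0 * np.pi / n_theta
    r0, c0 = lumen.center_rc

    coords = np.vstack([reg.coords for reg in struts]).astype(float)
    dr = coords[:, 0] - r0
    dc = coords[:, 1] - c0
    rad = np.hypot(dr, dc) / lumen.r_step_px
    th_idx = np.round((np.arctan2(dr, dc) % (2.0 * np.pi)) / d_theta)
    th_idx = th_idx.astype(int) % n_theta
    rad_idx = np.round(rad).astype(int)

    n_r = int(max(rad_idx.max(), np.ceil(lumen.radius_px.max()))) + 2
    rad_idx = np.clip(rad_idx, 0, n_r - 1)
    polar_struts = np.zeros((n_theta, n_r), dtype=bool)
    polar_struts[th_idx, rad_idx] = True

    # rectangular dilation: wrap-aware in theta, plain in r
    dilated = polar_struts.copy()
    for s in range(1, tangential_halfwidth + 1):
        dilated |= np.roll(polar_struts, s, axis=0)
        dilated |= np.roll(polar_struts, -s, axis=0)
    if radial_halfwidth > 0:
        base = dilated.copy()
        for s in range(1, radial_halfwidth + 1):
            shifted = np.zeros_like(base)
            shifted[:, s:] = base[:, :-s]
            dilated |= shifted
            shifted = np.zeros_like(base)
            shifted[:, :-s] = base[:, s:]
            dilated |= shifted

    has_strut = dilated.any(axis=1)
    outermost = (dilated * np.arange(n_r)).max(axis=1).astype(float)
    outermost *= lumen.r_step_px

    corrected = lumen.radius_px.copy()
    corrected[has_strut] = np.maximum(corrected[has_strut],
                                      outermost[has_strut])

    out = interpolate_contour(corrected, center_rc=lumen.center_rc,
                              r_step_px=lumen.r_step_px, smoothing=smoothing)
    return out.copy(corrected=True)
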