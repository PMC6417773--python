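"""Automatic pullback quality assessment from strut counts.

The number of struts visible per frame depends on the scaffold design and is
well described by a Gaussian across frames.  Its mean and standard deviation
are estimated once from reference (manual or ground-truth) counts.  A frame
whose detected-region count falls below the 5% quantile of that Gaussian is
labelled 'poor' (the detector evidently failed to find the expected struts);
a pullback with strictly more than a threshold number of poor frames is
classified 'poor' overall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "StrutCountModel",
    "QualityReport",
    "fit_strut_count_model",
    "classify_frame",
    "classify_pullback",
    "assess_pullback",
]


@dataclass
class StrutCountModel:
    """Gaussian model of the expected per-frame strut count."""

    mean: float
    sd: float
    quantile_level: float = 0.05

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive (model degenerate otherwise)")
        if not 0.0 < self.quantile_level < 1.0:
            raise ValueError("quantile_level must lie in (0, 1)")

    @property
    def cutoff(self) -> float:
        """The ``quantile_level`` quantile of Normal(mean, sd)."""
        return float(norm.ppf(self.quantile_level, loc=self.mean,
                              scale=self.sd))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"mean": self.mean, "sd": self.sd,
                       "quantile_level": self.quantile_level}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StrutCountModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_strut_count_model(counts: Sequence[int],
                          quantile_level: float = 0.05) -> StrutCountModel:
    """Sample mean / SD of reference per-frame strut counts (>= 10 frames)."""
    arr = np.asarray(list(counts), dtype=float)
    if arr.size < 10:
        raise ValueError(f"need at least 10 reference counts, got {arr.size}")
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise ValueError("reference counts have zero variance; "
                         "the Gaussian model is degenerate")
    return StrutCountModel(mean=float(arr.mean()), sd=sd,
                           quantile_level=quantile_level)


def classify_frame(detected_count: int, model: StrutCountModel) -> str:
    """'poor' iff the detected-region count is strictly below the cutoff."""
    if detected_count < 0:
        raise ValueError("detected_count must be non-negative")
    return "poor" if detected_count < model.cutoff else "ok"


def classify_pullback(frame_labels: Sequence[str],
                      threshold_frames: Optional[int] = 10,
                      threshold_fraction: Optional[float] = 0.20) -> str:
    """'poor' iff strictly more than the threshold number of frames are poor.

    The integer threshold wins when both forms are given; with
    ``threshold_frames=None`` the threshold is
    ``floor(threshold_fraction * n_frames)``.
    """
    n_poor = sum(1 for lab in frame_labels if lab == "poor")
    if threshold_frames is None:
        if threshold_fraction is None:
            raise ValueError("either threshold form must be given")
        threshold_frames = int(np.floor(threshold_fraction * len(frame_labels)))
    return "poor" if n_poor > threshold_frames else "good"


@dataclass
class QualityReport:
    """Per-frame labels and the pullback-level verdict."""

    counts: list[int]
    frame_labels: list[str]
    pullback_label: str
    frame_cutoff: float
    threshold_frames: int
    n_poor: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_poor = sum(1 for lab in self.frame_labels if lab == "poor")

    def summary(self) -> str:
        lines = [
            f"pullback quality: {self.pullback_label.upper()}",
            f"frames considered: {len(self.frame_labels)}",
            f"poor frames: {self.n_poor} "
            f"(threshold: > {self.threshold_frames})",
            f"per-frame cutoff: count < {self.frame_cutoff:.2f} struts",
        ]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "pullback_label": self.pullback_label,
                "n_poor": self.n_poor,
                "threshold_frames": self.threshold_frames,
                "frame_cutoff": self.frame_cutoff,
                "counts": list(map(int, self.counts)),
                "frame_labels": self.frame_labels,
            }, fh, indent=2)


def assess_pullback(counts: Sequence[int], model: StrutCountModel,
                    threshold_frames: Optional[int] = 10,
                    threshold_fraction: Optional[float] = 0.20) -> QualityReport:
    """Classify every frame and the pullback from detected strut counts."""
    labels = [classify_frame(int(c), model) for c in counts]
    verdict = classify_pullback(labels, threshold_frames=threshold_frames,
                                threshold_fraction=threshold_fraction)
    if threshold_frames is None:
        threshold_frames = int(np.floor((threshold_fraction or 0.2)
                                        * len(labels)))
    return QualityReport(counts=[int(c) for c in counts], frame_labels=labels,
                         pullback_label=verdict, frame_cutoff=model.cutoff,
                         threshold_frames=threshold_frames)
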