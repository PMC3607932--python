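"""Relative Archaea abundance from three-channel FISH label images.

Confocal images carry three probe channels: a universal bacterial mix (EUB),
a general archaeal probe (ARC915) and a Methanosaetaceae-specific probe
(MX825).  Quantification thresholds each channel, discards pixels positive
for both the bacterial and an archaeal probe (hybridization artefacts),
counts the archaeal area as ARC915-positive plus MX825-positive-not-ARC915
pixels (the general probe misses some Methanosaetaceae cells), and reports
the archaeal fraction of the total signal area.  Images with too little
signal area show dispersed cells rather than flocs and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

#: Default intensity threshold (8-bit images) and minimum signal area.
DEFAULT_THRESHOLD = 100
DEFAULT_MIN_AREA = 1000

CHANNELS = ("EUB", "ARC915", "MX825")


@dataclass
class LabelImageSet:
    """Three same-shape intensity rasters, one per probe channel."""

    image_id: str
    channels: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"missing channels: {missing}")
        shapes = {self.channels[c].shape for c in CHANNELS}
        if len(shapes) != 1:
            raise ValueError("channel rasters must share one shape")
        for c in CHANNELS:
            if (np.asarray(self.channels[c]) < 0).any():
                raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class AreaQuantification:
    """Per-image pixel areas and the archaeal percentage (or excluded)."""

    image_id: str
    area_bacteria: int
    area_archaea: int
    rel_archaea: Optional[float]  # percent; None when excluded

    @property
    def total_area(self) -> int:
        return self.area_bacteria + self.area_archaea

    @property
    def excluded(self) -> bool:
        return self.rel_archaea is None


def binarize(channel: np.ndarray, threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """Pixel mask: intensity strictly above the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return np.asarray(channel) > threshold


def quantify_image(
    images: LabelImageSet,
    threshold: int = DEFAULT_THRESHOLD,
    min_area: int = DEFAULT_MIN_AREA,
) -> AreaQuantification:
    """Quantify one image set.

    Double-positive pixels (bacterial AND an archaeal channel) are removed
    from every mask; the archaeal area is ARC915 plus MX825-not-ARC915, the
    bacterial area is EUB; the archaeal percentage is reported only when the
    combined signal area reaches ``min_area`` pixels.
    """
    e = binarize(images.channels["EUB"], threshold)
    a = binarize(images.channels["ARC915"], threshold)
    m = binarize(images.channels["MX825"], threshold)
    double = e & (a | m)
    e, a, m = e & ~double, a & ~double, m & ~double
    area_archaea = int(a.sum() + (m & ~a).sum())
    area_bacteria = int(e.sum())
    total = area_archaea + area_bacteria
    rel = 100.0 * area_archaea / total if total >= min_area else None
    return AreaQuantification(images.image_id, area_bacteria, area_archaea, rel)


def summarize(
    quantifications: Sequence[AreaQuantification],
    pooled: bool = False,
) -> tuple[float, float, int]:
    """Mean archaeal percentage, its sample SD, and the included-image count.

    By default this is the mean of per-image percentages over non-excluded
    images (SD = 0 for a single image).  With ``pooled=True`` the ratio of
    pooled areas is returned instead (SD then refers to the per-image values
    regardless).
    """
    included = [q for q in quantifications if not q.excluded]
    if not included:
        raise ValueError("all images excluded")
    values = np.array([q.rel_archaea for q in included], dtype=float)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    if pooled:
        arch = sum(q.area_archaea for q in included)
        total = sum(q.total_area for q in included)
        return 100.0 * arch / total, sd, len(included)
    return float(values.mean()), sd, len(included)
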