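"""Discoloration features: percent yellow and percent brown of the canopy.

Chlorosis turns leaf tissue from green toward yellow and, as necrosis
sets in, brown; the two fractions (Y%, B%) of canopy area are the
trait signature used by the classifier and severity stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

__all__ = ["HuePartition", "FeatureVector", "compute_features", "features_table"]


@dataclass(frozen=True)
class HuePartition:
    """Disjoint half-open hue bands (degrees) for brown, yellow, green."""

    brown: tuple = (10.0, 40.0)
    yellow: tuple = (40.0, 70.0)
    green: tuple = (70.0, 160.0)

    def __post_init__(self):
        bands = sorted([self.brown, self.yellow, self.green])
        for (lo, hi) in bands:
            if not (0.0 <= lo < hi <= 360.0):
                raise ValueError(f"invalid hue band [{lo}, {hi})")
        for (_, hi), (lo2, _) in zip(bands, bands[1:]):
            if lo2 < hi:
                raise ValueError("hue bands must be disjoint")


@dataclass(frozen=True)
class FeatureVector:
    """(Y%, B%): percent of canopy pixels in the yellow / brown hue band."""

    yellow_pct: float
    brown_pct: float

    def __post_init__(self):
        if not (0.0 <= self.yellow_pct <= 100.0 and 0.0 <= self.brown_pct <= 100.0):
            raise ValueError("percentages must lie in [0, 100]")
        if self.yellow_pct + self.brown_pct > 100.0 + 1e-9:
            raise ValueError("yellow_pct + brown_pct cannot exceed 100")

    def as_array(self) -> np.ndarray:
        return np.array([self.yellow_pct, self.brown_pct])


def compute_features(
    image: np.ndarray,
    mask: np.ndarray,
    partition: HuePartition | None = None,
) -> FeatureVector:
    """Percent yellow / brown pixels of the masked canopy.

    Pixels inside the mask whose hue falls in none of the three bands
    count toward the denominator only, so Y% + B% <= 100 always holds.
    Raises ``ValueError`` on an empty mask: a silent (0, 0) would be
    indistinguishable from a perfectly green canopy.
    """
    partition = partition or HuePartition()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no canopy pixels to measure")
    rgb = np.asarray(image)[mask].astype(float) / 255.0
    hue = rgb2hsv(rgb.reshape(1, -1, 3))[0, :, 0] * 360.0
    total = hue.size
    ylo, yhi = partition.yellow
    blo, bhi = partition.brown
    n_yellow = int(((hue >= ylo) & (hue < yhi)).sum())
    n_brown = int(((hue >= blo) & (hue < bhi)).sum())
    return FeatureVector(
        yellow_pct=100.0 * n_yellow / total, brown_pct=100.0 * n_brown / total
    )


def features_table(images_masks, ids=None, partition=None) -> pd.DataFrame:
    """Feature rows for an iterable of ``(image, mask)`` pairs."""
    rows = []
    for i, (image, mask) in enumerate(images_masks):
        fv = compute_features(image, mask, partition)
        rows.append(
            {
                "image_id": ids[i] if ids is not None else i,
                "yellow_pct": fv.yellow_pct,
                "brown_pct": fv.brown_pct,
            }
        )
    return pd.DataFrame(rows)
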