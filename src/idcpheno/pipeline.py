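"""Canopy segmentation: calibration, HSV thresholding, mask cleanup.

The foreground (plant) is separated from soil by excluding pixels whose
saturation falls below a threshold or whose hue lies outside a kept
range (soil is gray; a canopy is green through brown).  Small connected
components left after thresholding — debris, weeds — are removed by
keeping only the largest component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import label as cc_label

__all__ = [
    "HSVImage",
    "SegmentationParams",
    "CalibrationTransform",
    "rgb_to_hsv",
    "fit_calibration",
    "apply_calibration",
    "threshold_segment",
    "clean_mask",
    "preprocess",
    "NoForegroundError",
]


class NoForegroundError(ValueError):
    """Raised when segmentation leaves no foreground pixel."""


@dataclass
class HSVImage:
    """Hue in degrees [0, 360); saturation and value in [0, 1]."""

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray


@dataclass
class SegmentationParams:
    """Per-pixel keep rule: ``sat >= saturation_min`` and hue in a kept range.

    Defaults keep brown through green (10-160 deg) at saturation >= 0.15,
    the band where soil (gray, low saturation) drops out.  Ranges are
    half-open ``[lo, hi)`` degree intervals.
    """

    saturation_min: float = 0.15
    keep_hue_ranges: tuple = ((10.0, 160.0),)

    def __post_init__(self):
        ivs = sorted(self.keep_hue_ranges)
        for lo, hi in ivs:
            if not (0.0 <= lo < hi <= 360.0):
                raise ValueError(f"invalid hue interval [{lo}, {hi})")
        for (_, hi), (lo2, _) in zip(ivs, ivs[1:]):
            if lo2 < hi:
                raise ValueError("keep_hue_ranges must not overlap")


@dataclass
class CalibrationTransform:
    """Per-channel affine correction ``out = gain * in + offset``."""

    gain: np.ndarray = field(default_factory=lambda: np.ones(3))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def is_identity(self) -> bool:
        return np.allclose(self.gain, 1.0) and np.allclose(self.offset, 0.0)


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB array")
    if image.shape[0] < 16 or image.shape[1] < 16:
        raise ValueError("image must be at least 16 x 16")
    return image


def rgb_to_hsv(image: np.ndarray) -> HSVImage:
    """Standard hexcone RGB -> HSV; hue returned in degrees."""
    image = _check_rgb(image)
    hsv = rgb2hsv(image.astype(float) / 255.0)
    return HSVImage(hue=hsv[..., 0] * 360.0, saturation=hsv[..., 1],
                    value=hsv[..., 2])


def fit_calibration(
    chart_observed: np.ndarray, chart_reference: np.ndarray
) -> CalibrationTransform:
    """Least-squares per-channel affine map from 24 color-chart patches.

    ``chart_observed`` and ``chart_reference`` are (24, 3) mean patch
    RGBs.  A degenerate channel (zero variance in the observed patches)
    falls back to the identity with a warning.
    """
    obs = np.asarray(chart_observed, dtype=float)
    ref = np.asarray(chart_reference, dtype=float)
    if obs.shape != ref.shape or obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("chart arrays must both be (n_patches, 3)")
    gain = np.ones(3)
    offset = np.zeros(3)
    for c in range(3):
        x, y = obs[:, c], ref[:, c]
        vx = x.var()
        if vx < 1e-12:
            warnings.warn(
                f"calibration channel {c}: observed patches are constant; "
                "using identity", stacklevel=2,
            )
            continue
        g = np.cov(x, y, bias=True)[0, 1] / vx
        gain[c] = g
        offset[c] = y.mean() - g * x.mean()
    return CalibrationTransform(gain=gain, offset=offset)


def apply_calibration(image: np.ndarray, cal: CalibrationTransform) -> np.ndarray:
    image = _check_rgb(image)
    out = image.astype(float) * cal.gain + cal.offset
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def threshold_segment(hsv: HSVImage, params: SegmentationParams | None = None
                      ) -> np.ndarray:
    """Boolean mask: saturation above threshold and hue inside a kept range."""
    params = params or SegmentationParams()
    keep = np.zeros_like(hsv.hue, dtype=bool)
    for lo, hi in params.keep_hue_ranges:
        keep |= (hsv.hue >= lo) & (hsv.hue < hi)
    return keep & (hsv.saturation >= params.saturation_min)


def clean_mask(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Keep only the largest connected component of ``mask``.

    Connectivity 2 counts diagonal neighbours (8-connectivity); 1 is
    4-connectivity.  Equal-area ties go to the component whose first
    pixel comes earliest in row-major order (scikit-image assigns
    labels in that order, so the smallest label wins).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoForegroundError("no foreground found: mask is empty")
    labels = cc_label(mask, connectivity=connectivity)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    keep = int(np.argmax(counts))  # first max = earliest-labeled component
    return labels == keep


def preprocess(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    calibration: CalibrationTransform | None = None,
    connectivity: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Full preprocessing: calibrate, threshold in HSV, keep largest blob.

    Returns ``(masked_rgb, mask)`` where ``masked_rgb`` is the original
    (calibrated) image with background pixels zeroed.  Raises
    :class:`NoForegroundError` when thresholding removes every pixel.
    """
    image = _check_rgb(image)
    if calibration is not None and not calibration.is_identity():
        image = apply_calibration(image, calibration)
    raw = threshold_segment(rgb_to_hsv(image), params)
    mask = clean_mask(raw, connectivity=connectivity)
    masked = image.copy()
    masked[~mask] = 0
    return masked, mask
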