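"""Synthetic soybean canopy images with exact ground truth.

Top-down RGB plots are emulated as a single connected blob of leaflet
disks over a low-saturation soil texture, with optional small debris
blobs on the soil.  The generator controls, pixel-exactly, which
fraction of the canopy carries chlorotic (yellow) or necrotic (brown)
hue, so every downstream imaging stage can be validated against an
exact pixel-count oracle.

Hue bands follow the extraction defaults (brown 10-40deg, yellow
40-70deg, green 70-160deg); colors are drawn from band *interiors* so
8-bit quantisation cannot move a pixel across a band boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.color import hsv2rgb

__all__ = [
    "SyntheticCanopySpec",
    "GroundTruth",
    "generate_canopy",
    "label_from_features",
    "sample_labeled_features",
    "generate_labeled_images",
    "write_image_set",
]

# Soil triples: grayish-brown, saturation <= ~0.08 so the default
# segmentation threshold (0.15) excludes soil by construction.
DEFAULT_SOIL_PALETTE = (
    (120, 114, 111),
    (134, 128, 124),
    (104, 100, 97),
    (146, 141, 135),
    (92, 88, 86),
)

# Interior hue bands (degrees) used for painting; each sits >=5deg
# inside the nominal partition so quantisation noise stays in-band.
_GREEN_PAINT = (95.0, 140.0)
_YELLOW_PAINT = (48.0, 62.0)
_BROWN_PAINT = (18.0, 32.0)

# Nominal partition used for the ground-truth recount (must agree with
# idcpheno.features.HuePartition defaults).
_BAND_YELLOW = (40.0, 70.0)
_BAND_BROWN = (10.0, 40.0)


@dataclass(frozen=True)
class SyntheticCanopySpec:
    """Parameters of one synthetic canopy image.

    ``yellow_frac`` and ``brown_frac`` are target proportions of canopy
    pixels (the realised ground truth is re-counted from the emitted
    image).  ``illumination_jitter`` is a multiplicative half-range:
    every pixel's value channel is scaled by U(1-j, 1+j).
    """

    width: int = 160
    height: int = 160
    canopy_radius: int = 50
    n_leaflets: int = 9
    yellow_frac: float = 0.0
    brown_frac: float = 0.0
    soil_palette: tuple = DEFAULT_SOIL_PALETTE
    n_debris: int = 3
    debris_size: int = 7
    illumination_jitter: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.yellow_frac <= 1.0 and 0.0 <= self.brown_frac <= 1.0):
            raise ValueError("yellow_frac and brown_frac must lie in [0, 1]")
        if self.yellow_frac + self.brown_frac > 1.0 + 1e-12:
            raise ValueError("yellow_frac + brown_frac must not exceed 1")
        if self.width < 16 or self.height < 16:
            raise ValueError("image must be at least 16x16 pixels")
        # leaflets extend to ~1.15 R; require head-room inside the frame
        if 1.2 * self.canopy_radius >= min(self.width, self.height) / 2:
            raise ValueError("canopy larger than frame: reduce canopy_radius")
        if self.n_debris > 0 and self.debris_size >= self.canopy_radius:
            raise ValueError("debris_size must be smaller than canopy_radius")


@dataclass
class GroundTruth:
    """Exact per-image truth: masks and discoloration percentages."""

    canopy_mask: np.ndarray
    true_yellow_pct: float
    true_brown_pct: float
    debris_mask: np.ndarray


def _disk(mask: np.ndarray, cy: float, cx: float, r: float) -> None:
    h, w = mask.shape
    yy, xx = np.ogrid[:h, :w]
    mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _paint_hsv(
    rng: np.random.Generator,
    n: int,
    hue_range: tuple[float, float],
    sat_range=(0.55, 0.85),
    val_range=(0.45, 0.80),
) -> np.ndarray:
    h = rng.uniform(hue_range[0] / 360.0, hue_range[1] / 360.0, n)
    s = rng.uniform(*sat_range, n)
    v = rng.uniform(*val_range, n)
    return np.stack([h, s, v], axis=-1)


def generate_canopy(spec: SyntheticCanopySpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one canopy image and its exact ground truth.

    Returns ``(image, truth)`` where ``image`` is H x W x 3 uint8.
    Identical spec (including seed) yields a bit-identical image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    cy, cx = h / 2.0, w / 2.0
    R = float(spec.canopy_radius)

    # --- canopy mask: central disk plus overlapping leaflet disks -----
    canopy = np.zeros((h, w), dtype=bool)
    _disk(canopy, cy, cx, 0.55 * R)
    for _ in range(max(spec.n_leaflets, 0)):
        ang = rng.uniform(0, 2 * np.pi)
        d = rng.uniform(0.30 * R, 0.65 * R)
        rr = rng.uniform(0.35 * R, 0.50 * R)
        _disk(canopy, cy + d * np.sin(ang), cx + d * np.cos(ang), rr)
    area = int(canopy.sum())

    # --- soil background ---------------------------------------------
    palette = np.asarray(spec.soil_palette, dtype=float)
    pick = rng.integers(0, len(palette), size=h * w)
    soil = palette[pick].reshape(h, w, 3)
    jit = rng.uniform(
        1 - spec.illumination_jitter, 1 + spec.illumination_jitter, size=(h, w, 1)
    )
    image = np.clip(soil * jit, 0, 255)

    # --- canopy paint: exact pixel counts per hue band ----------------
    n_yellow = int(round(spec.yellow_frac * area))
    n_brown = int(round(spec.brown_frac * area))
    n_yellow = min(n_yellow, area)
    n_brown = min(n_brown, area - n_yellow)
    order = rng.permutation(area)
    ys, xs = np.nonzero(canopy)
    ys, xs = ys[order], xs[order]
    hsv = np.empty((area, 3), dtype=float)
    hsv[:n_yellow] = _paint_hsv(rng, n_yellow, _YELLOW_PAINT)
    hsv[n_yellow : n_yellow + n_brown] = _paint_hsv(rng, n_brown, _BROWN_PAINT)
    hsv[n_yellow + n_brown :] = _paint_hsv(rng, area - n_yellow - n_brown, _GREEN_PAINT)
    rgb = hsv2rgb(hsv.reshape(1, -1, 3)).reshape(-1, 3) * 255.0
    vjit = rng.uniform(
        1 - spec.illumination_jitter, 1 + spec.illumination_jitter, size=(area, 1)
    )
    image[ys, xs] = np.clip(rgb * vjit, 0, 255)

    # --- debris: small brown blobs on the soil, disjoint from canopy --
    debris = np.zeros((h, w), dtype=bool)
    rad = max(spec.debris_size / 2.0, 1.0)
    placed = 0
    attempts = 0
    while placed < spec.n_debris:
        attempts += 1
        if attempts > 500:
            raise ValueError(
                "could not place all debris blobs; enlarge the frame or "
                "reduce n_debris/debris_size"
            )
        dy = rng.uniform(rad + 1, h - rad - 1)
        dx = rng.uniform(rad + 1, w - rad - 1)
        # keep a >1 px gap to the canopy so components stay disjoint
        if np.hypot(dy - cy, dx - cx) < 1.20 * R + rad + 2:
            continue
        blob = np.zeros_like(debris)
        _disk(blob, dy, dx, rad)
        if (blob & debris).any():
            continue
        n_blob = int(blob.sum())
        bhsv = _paint_hsv(rng, n_blob, _BROWN_PAINT, sat_range=(0.45, 0.75),
                          val_range=(0.35, 0.65))
        image[blob] = np.clip(hsv2rgb(bhsv.reshape(1, -1, 3)).reshape(-1, 3) * 255.0,
                              0, 255)
        debris |= blob
        placed += 1

    image = np.round(image).astype(np.uint8)

    # --- ground truth by exact recount on the emitted image -----------
    from skimage.color import rgb2hsv  # local import to avoid cycle at module load

    hue = rgb2hsv(image[canopy].reshape(1, -1, 3) / 255.0)[0, :, 0] * 360.0
    ny = int(((hue >= _BAND_YELLOW[0]) & (hue < _BAND_YELLOW[1])).sum())
    nb = int(((hue >= _BAND_BROWN[0]) & (hue < _BAND_BROWN[1])).sum())
    truth = GroundTruth(
        canopy_mask=canopy,
        true_yellow_pct=100.0 * ny / area,
        true_brown_pct=100.0 * nb / area,
        debris_mask=debris,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Labeled fixture sets for the classifier / severity stages
# ---------------------------------------------------------------------------

def label_from_features(yellow_pct: float, brown_pct: float) -> int:
    """Fixture label rule mapping (Y%, B%) to an ordinal score 1-5.

    Cutoffs are generator parameters of the synthetic study, evaluated
    most-severe first: necrosis >= 15% is a 5; heavy chlorosis
    (Y >= 50) or moderate necrosis (B >= 5) is a 4; and so on.
    """
    if brown_pct >= 15:
        return 5
    if yellow_pct >= 50 or brown_pct >= 5:
        return 4
    if yellow_pct >= 25 or brown_pct >= 2:
        return 3
    if yellow_pct >= 5 or brown_pct >= 1:
        return 2
    return 1


# Class-conditional (mean, sd) for (Y%, B%) plus the box each class must
# stay inside so the label rule reproduces the intended class.  The
# boxes are separated by >= 5 within-class standard deviations.
_CLASS_CLUSTERS = {
    1: ((2.0, 0.6, 0.0, 4.5), (0.30, 0.12, 0.0, 0.9)),
    2: ((14.0, 1.6, 5.0, 24.5), (0.80, 0.18, 0.0, 0.9)),
    3: ((36.0, 1.8, 25.0, 49.5), (2.80, 0.35, 0.0, 4.9)),
    4: ((60.0, 1.8, 50.0, 75.0), (9.00, 0.90, 5.0, 14.5)),
    5: ((30.0, 3.0, 10.0, 55.0), (25.0, 1.8, 15.0, 45.0)),
}
# Mild imbalance echoing field panels dominated by healthy plots.
_CLASS_PRIORS = {1: 0.32, 2: 0.20, 3: 0.16, 4: 0.16, 5: 0.16}


def sample_labeled_features(
    n: int, seed: int = 0, priors: dict[int, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (Y%, B%) feature pairs with labels from the fixture rule.

    Class-conditional clusters are >= 5 sd apart, so the set is linearly
    separable in practice.  Returns ``(features, labels)`` with features
    shaped (n, 2) as columns (yellow_pct, brown_pct).
    """
    rng = np.random.default_rng(seed)
    priors = priors or _CLASS_PRIORS
    classes = np.array(sorted(priors))
    probs = np.array([priors[c] for c in classes], dtype=float)
    probs /= probs.sum()
    labels = rng.choice(classes, size=n, p=probs)
    feats = np.empty((n, 2))
    for c in classes:
        idx = labels == c
        (ym, ysd, ylo, yhi), (bm, bsd, blo, bhi) = _CLASS_CLUSTERS[c]
        feats[idx, 0] = np.clip(rng.normal(ym, ysd, idx.sum()), ylo, yhi)
        feats[idx, 1] = np.clip(rng.normal(bm, bsd, idx.sum()), blo, bhi)
    derived = np.array([label_from_features(y, b) for y, b in feats])
    assert (derived == labels).all(), "cluster boxes must respect the label rule"
    return feats, labels


def generate_labeled_images(
    n: int, seed: int = 0, base: SyntheticCanopySpec | None = None
):
    """Yield ``(image, truth, label)`` for a labeled synthetic image set.

    Target fractions are sampled from the class clusters; the label is
    re-derived from the exact ground-truth percentages so the emitted
    label always matches the image content.
    """
    base = base or SyntheticCanopySpec()
    feats, _ = sample_labeled_features(n, seed=seed)
    for i, (y_pct, b_pct) in enumerate(feats):
        spec = replace(
            base,
            yellow_frac=float(y_pct) / 100.0,
            brown_frac=float(b_pct) / 100.0,
            seed=seed * 1_000_003 % (2**31) + i,
        )
        image, truth = generate_canopy(spec)
        label = label_from_features(truth.true_yellow_pct, truth.true_brown_pct)
        yield image, truth, label


def write_image_set(out_dir, n: int, seed: int = 0,
                    base: SyntheticCanopySpec | None = None) -> Path:
    """Write PNG images plus a CSV manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["image", "true_yellow_pct", "true_brown_pct", "label"])
        for i, (image, truth, label) in enumerate(
            generate_labeled_images(n, seed=seed, base=base)
        ):
            name = f"canopy_{i:04d}.png"
            iio.imwrite(out / name, image)
            wr.writerow([name, f"{truth.true_yellow_pct:.4f}",
                         f"{truth.true_brown_pct:.4f}", label])
    return manifest
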