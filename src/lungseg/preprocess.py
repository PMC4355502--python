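"""Radiograph container and machine-profile standardization.

Radiographs from mobile machines come with a dark detector border, text
labels, and sometimes an inverted grayscale. This module normalizes all of
them to the working convention used by the rest of the pipeline: bright
bone / mediastinum, dark (radiolucent) lungs, chest area filling the frame.

Coordinates are 0-based, half-open, row-major, row 0 at top — everywhere in
this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

PROFILES = ("standard", "background", "inverted_background", "auto")


@dataclass
class Radiograph:
    """A 2-D grayscale radiograph with pixels normalized to [0, 1].

    Attributes
    ----------
    pixels
        Float array, shape ``(r0, c0)``, values in [0, 1].
    profile
        Acquisition profile: ``standard`` (PA erect, stationary machine),
        ``background`` (mobile, dark detector border), ``inverted_background``
        (mobile, inverted grayscale plus border) or ``auto`` (detect).
    source_bit_depth
        Bit depth of the source file (8, 12 or 16); informational.
    """

    pixels: np.ndarray
    profile: str = "standard"
    source_bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("radiograph pixels must be a 2-D array")
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise ValueError("radiograph must be at least 64x64")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("radiograph contains non-finite pixels")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("radiograph pixels must lie in [0, 1]")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")

    @property
    def r0(self) -> int:
        return self.pixels.shape[0]

    @property
    def c0(self) -> int:
        return self.pixels.shape[1]


@dataclass
class CropResult:
    """Cropped radiograph plus the bounding box in input coordinates.

    ``bbox`` is ``(row_min, row_max, col_min, col_max)``, 0-based half-open.
    """

    image: Radiograph
    bbox: tuple[int, int, int, int]


def detect_inversion(img: Radiograph) -> bool:
    """Judge whether a radiograph is intensity-inverted.

    Anatomy-based statistic: in normal display polarity the mediastinum /
    spine column (central vertical strip) is brighter than the radiolucent
    lung flanks; in an inverted image the relation flips. Both strips sit
    inside the chest, so detector borders and labels do not disturb the
    comparison. Ties break toward "not inverted" so a uniform image is left
    untouched.
    """
    p = img.pixels
    r0, c0 = p.shape
    rows = slice(int(0.20 * r0), int(0.80 * r0))
    center_strip = p[rows, int(0.45 * c0) : int(0.55 * c0)]
    flanks = np.concatenate(
        [
            p[rows, int(0.20 * c0) : int(0.35 * c0)].ravel(),
            p[rows, int(0.65 * c0) : int(0.80 * c0)].ravel(),
        ]
    )
    return bool(np.median(center_strip) < np.median(flanks))


def detect_background(img: Radiograph, border: int = 10) -> bool:
    """Judge whether the frame carries a dark mobile-detector border.

    Called after polarity normalization; true when the border ring is darker
    than half the central-quarter median.
    """
    p = img.pixels
    r0, c0 = p.shape
    ring = np.concatenate(
        [
            p[:border, :].ravel(),
            p[-border:, :].ravel(),
            p[border:-border, :border].ravel(),
            p[border:-border, -border:].ravel(),
        ]
    )
    center = p[r0 // 4 : 3 * r0 // 4, c0 // 4 : 3 * c0 // 4]
    return bool(np.median(ring) < 0.5 * np.median(center))


def invert(img: Radiograph) -> Radiograph:
    """Elementwise intensity inversion, ``out = 1 - in``."""
    return replace(img, pixels=1.0 - img.pixels)


def stretch_contrast(img: Radiograph, clip_total: float = 0.02) -> Radiograph:
    """Histogram stretch saturating ``clip_total`` of the pixels (split per tail).

    The ``clip_total/2`` and ``1 - clip_total/2`` intensity percentiles map to
    0 and 1; values beyond them saturate. A constant (degenerate) image is
    returned unchanged.
    """
    if not 0.0 <= clip_total < 1.0:
        raise ValueError("clip_total must be in [0, 1)")
    p = img.pixels
    lo, hi = np.percentile(p, [100.0 * clip_total / 2.0, 100.0 * (1.0 - clip_total / 2.0)])
    if hi <= lo:
        return replace(img, pixels=p.copy())
    out = np.clip((p - lo) / (hi - lo), 0.0, 1.0)
    return replace(img, pixels=out)


def crop_chest(img: Radiograph, dilate_frac: float = 0.01) -> CropResult:
    """Remove the mobile-detector background and text labels, crop to the chest.

    Otsu-binarize (bright class = body), dilate with a disk of radius
    ``dilate_frac * min(r0, c0)`` (>= 3 px) to preserve coverage, keep the
    largest connected component plus any component overlapping its bounding
    box (labels printed outside the chest are dropped), and crop to the
    bounding box of what remains. If thresholding leaves no foreground the
    full frame is returned with a warning.
    """
    p = img.pixels
    r0, c0 = p.shape
    if p.max() <= p.min():
        warnings.warn("crop_chest: empty foreground, returning full frame")
        return CropResult(image=replace(img, pixels=p.copy()), bbox=(0, r0, 0, c0))
    t = threshold_otsu(p, nbins=256)
    fg = p > t
    if not fg.any():
        warnings.warn("crop_chest: empty foreground, returning full frame")
        return CropResult(image=replace(img, pixels=p.copy()), bbox=(0, r0, 0, c0))
    radius = max(3, int(round(dilate_frac * min(r0, c0))))
    dilated = ndi.binary_dilation(fg, structure=disk(radius).astype(bool))
    lab = label(dilated, connectivity=2)
    regions = regionprops(lab)
    main = max(regions, key=lambda r: r.area)
    mr0, mc0, mr1, mc1 = main.bbox
    keep = np.zeros_like(fg)
    for reg in regions:
        a0, b0, a1, b1 = reg.bbox
        overlaps = a0 < mr1 and a1 > mr0 and b0 < mc1 and b1 > mc0
        if reg.label == main.label or overlaps:
            keep |= lab == reg.label
    # the dilation merges faint edges into their component; the crop box is
    # taken from the undilated foreground of the kept components so the
    # dilation radius does not leak background into the chest frame
    keep &= fg
    rows = np.flatnonzero(keep.any(axis=1))
    cols = np.flatnonzero(keep.any(axis=0))
    bbox = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    cropped = p[bbox[0] : bbox[1], bbox[2] : bbox[3]]
    return CropResult(image=replace(img, pixels=cropped.copy()), bbox=bbox)


def standardize(img: Radiograph, profile: str | None = None) -> tuple[Radiograph, dict]:
    """Full pre-processing chain: polarity, cropping, contrast.

    Resolves ``auto`` via :func:`detect_inversion` / :func:`detect_background`,
    inverts if needed, crops background profiles, then stretches the contrast.
    Returns the standardized radiograph and a record of what was done
    (resolved profile, inversion flag, crop bbox).
    """
    profile = profile or img.profile
    record: dict = {"requested_profile": profile}
    if profile == "auto":
        inverted = detect_inversion(img)
        if inverted:
            img = invert(img)
        has_background = detect_background(img)
        profile = (
            "inverted_background"
            if (inverted and has_background)
            else "background"
            if has_background
            else "standard"
        )
    else:
        inverted = profile == "inverted_background"
        if inverted:
            img = invert(img)
    record["profile"] = profile
    record["inverted"] = inverted
    if profile in ("background", "inverted_background"):
        crop = crop_chest(img)
        img = crop.image
        record["bbox"] = crop.bbox
    else:
        record["bbox"] = (0, img.r0, 0, img.c0)
    img = stretch_contrast(img)
    return replace(img, profile="standard"), record


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Binary hole filling by background flood from the frame."""
    return ndi.binary_fill_holes(mask)
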