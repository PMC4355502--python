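"""Fill the estimated lung outline into a solid mask.

The outline from the rule system is only a border sketch. To make it solid:
the pre-processed image is sharpened with high-frequency emphasis filtering
(HFEF) and histogram-equalized, heavily blurred (32x32 Gaussian, sigma=10),
and globally Otsu-thresholded, keeping the darker (lung) class -> I_th. The
convex hull of the outline, L_CH, restricts I_th to the chest region
(I_th_roi), and the union of outline and I_th_roi is closed morphologically
(dilate, fill holes, erode, drop small regions) into the estimated lung mask
L_mask. This stage runs at 256x256.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.exposure import equalize_hist
from skimage.filters import threshold_otsu
from skimage.morphology import disk


@dataclass
class FillIntermediates:
    """Every intermediate of the outline-filling stage, for inspection."""

    i_hfef: np.ndarray
    i_smooth: np.ndarray
    i_th: np.ndarray
    l_ch: np.ndarray
    i_th_roi: np.ndarray
    l_mask: np.ndarray


class EmptyOutlineError(ValueError):
    """Raised when the outline is empty and the fill stage cannot proceed."""


def hfef(
    img: np.ndarray,
    k1: float = 0.5,
    k2: float = 1.5,
    d0_frac: float = 0.25,
    equalize: bool = True,
) -> np.ndarray:
    """High-frequency emphasis filtering with optional histogram equalization.

    Frequency-domain transfer function ``H = k1 + k2 * H_hp`` with a Gaussian
    high-pass ``H_hp = 1 - exp(-D^2 / (2 D0^2))``, cutoff ``D0 = d0_frac *
    width`` in frequency-sample units. With ``k2=0, equalize=False`` the
    output is ``k1 * img`` (identity limit).
    """
    img = np.asarray(img, dtype=np.float64)
    if img.max() <= img.min():
        return img.copy()
    rows, cols = img.shape
    fu = np.fft.fftfreq(rows)[:, None] * rows
    fv = np.fft.fftfreq(cols)[None, :] * cols
    d2 = fu * fu + fv * fv
    d0 = d0_frac * cols
    h = k1 + k2 * (1.0 - np.exp(-d2 / (2.0 * d0 * d0)))
    out = np.real(np.fft.ifft2(np.fft.fft2(img) * h))
    if equalize:
        out = equalize_hist(out)
    return out


def _blur_kernel_1d(size: int = 32, sigma: float = 10.0) -> np.ndarray:
    # even-sized kernel centered between taps (symmetric half-sample offsets)
    offsets = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-offsets * offsets / (2.0 * sigma * sigma))
    return g / g.sum()


def smooth(img: np.ndarray, size: int = 32, sigma: float = 10.0) -> np.ndarray:
    """Separable Gaussian blur with a ``size`` x ``size`` kernel, replicate borders.

    The kernel is normalized (mass-conserving). An even ``size`` implies a
    half-pixel grid offset, shared by everything downstream.
    """
    k = _blur_kernel_1d(size, sigma)
    out = ndi.convolve1d(np.asarray(img, dtype=np.float64), k, axis=0, mode="nearest")
    return ndi.convolve1d(out, k, axis=1, mode="nearest")


def otsu(img: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Global Otsu threshold; the darker class is kept as lung foreground.

    A constant (unimodal) image yields an empty mask with a warning.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.max() <= img.min():
        warnings.warn("otsu: constant image, returning empty mask")
        return np.zeros(img.shape, dtype=bool)
    t = threshold_otsu(img, nbins=nbins)
    return img < t


def hull_vertices(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices of integer (row, col) points, counter-clockwise.

    Andrew's monotone chain in exact integer arithmetic; collinear boundary
    points are excluded. Returns an (m, 2) array ordered counter-clockwise in
    (x=col, y=row) coordinates. Degenerate inputs (all points collinear)
    return the input extremes.
    """
    pts = np.unique(np.asarray(points, dtype=np.int64), axis=0)
    if len(pts) <= 2:
        return pts
    # sort by (col, row) i.e. (x, y)
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    p = pts[order][:, ::-1]  # (x, y)

    def cross(o, a, b) -> int:
        return int((a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0]))

    lower: list = []
    for q in p:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], q) <= 0:
            lower.pop()
        lower.append(q)
    upper: list = []
    for q in p[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], q) <= 0:
            upper.pop()
        upper.append(q)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:  # all collinear
        return np.array([[q[1], q[0]] for q in (p[0], p[-1])], dtype=np.int64)
    return np.array([[q[1], q[0]] for q in hull], dtype=np.int64)  # back to (row, col)


def convex_hull_mask(l_outline: np.ndarray) -> np.ndarray:
    """Filled convex hull of the foreground pixel centers, on the same grid.

    A pixel belongs to the hull mask iff its center lies inside or on the
    hull polygon (exact integer half-plane tests). Raises
    :class:`EmptyOutlineError` on an empty outline; a collinear outline is
    returned unchanged.
    """
    mask = np.asarray(l_outline, dtype=bool)
    if not mask.any():
        raise EmptyOutlineError("cannot take the convex hull of an empty outline")
    pts = np.argwhere(mask)
    verts = hull_vertices(pts)
    if len(verts) < 3:
        return mask.copy()
    r0, c0 = mask.shape
    rr, cc = np.mgrid[0:r0, 0:c0]
    rr = rr.astype(np.int64)
    cc = cc.astype(np.int64)
    inside = np.ones(mask.shape, dtype=bool)
    m = len(verts)
    for i in range(m):
        ar, ac = verts[i]
        br, bc = verts[(i + 1) % m]
        # counter-clockwise polygon in (x=col, y=row): interior where cross >= 0
        cross = (bc - ac) * (rr - ar) - (br - ar) * (cc - ac)
        inside &= cross >= 0
    return inside


def build_mask(
    l_outline: np.ndarray,
    i_th_roi: np.ndarray,
    selem_frac: float = 0.02,
    min_region_frac: float = 0.01,
) -> np.ndarray:
    """Union, dilate, fill holes, erode, drop small regions -> L_mask."""
    union = np.asarray(l_outline, dtype=bool) | np.asarray(i_th_roi, dtype=bool)
    if not union.any():
        warnings.warn("build_mask: empty union, returning empty mask")
        return union
    radius = max(1, int(round(selem_frac * union.shape[1])))
    selem = disk(radius).astype(bool)
    out = ndi.binary_dilation(union, structure=selem)
    out = ndi.binary_fill_holes(out)
    out = ndi.binary_erosion(out, structure=selem)
    size = out.shape[0] * out.shape[1]
    lab, n = ndi.label(out, structure=np.ones((3, 3), dtype=int))
    if n:
        areas = np.bincount(lab.ravel())
        keep = np.flatnonzero(areas >= min_region_frac * size)
        keep = keep[keep != 0]
        out = np.isin(lab, keep)
    return out


def fill_outline(
    img: np.ndarray,
    l_outline: np.ndarray,
    k1: float = 0.5,
    k2: float = 1.5,
    d0_frac: float = 0.25,
    blur_size: int = 32,
    blur_sigma: float = 10.0,
    selem_frac: float = 0.02,
    min_region_frac: float = 0.01,
) -> FillIntermediates:
    """Run the full filling stage; image and outline must share a shape."""
    if img.shape != l_outline.shape:
        raise ValueError("image and outline must share a shape")
    i_hfef = hfef(img, k1=k1, k2=k2, d0_frac=d0_frac)
    i_smooth = smooth(i_hfef, size=blur_size, sigma=blur_sigma)
    i_th = otsu(i_smooth)
    l_ch = convex_hull_mask(l_outline)
    i_th_roi = i_th & l_ch
    l_mask = build_mask(l_outline, i_th_roi, selem_frac=selem_frac, min_region_frac=min_region_frac)
    return FillIntermediates(
        i_hfef=i_hfef, i_smooth=i_smooth, i_th=i_th, l_ch=l_ch, i_th_roi=i_th_roi, l_mask=l_mask
    )
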