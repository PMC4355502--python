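"""Synthetic chest-radiograph phantoms with known ground-truth lung masks.

The phantom emulates the structures the segmentation pipeline has to cope
with on a PA/AP chest film, in the standard display polarity (bright bone,
dark air): a soft-tissue thorax filling the frame, a bright mediastinum /
spine band, two darker tilted elliptical lung fields truncated below by
diaphragm domes (with costophrenic angles where dome meets ellipse), bright
parabolic rib bands of limited contrast crossing the lungs, clavicle bands
near the apex, optional consolidation blobs, and additive Gaussian noise.

Mobile-machine variants wrap the standard phantom the way portable detectors
do: ``background`` pads a dark border carrying bright text-like glyph blocks
outside the chest; ``inverted_background`` additionally inverts the
grayscale. The ground truth is the exact analytic lung region (ellipses
minus the area below the diaphragm domes), so every pipeline stage can be
scored without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from lungseg import io as lio
from lungseg.preprocess import Radiograph

VARIANTS = ("standard", "background", "inverted_background")


class PhantomConfigError(ValueError):
    """Invalid phantom geometry or intensity configuration."""


@dataclass(frozen=True)
class LungSpec:
    """One lung field: center / semi-axes in fractional image coordinates."""

    center: tuple[float, float]  # (row_frac, col_frac)
    semi_axes: tuple[float, float]  # (row_frac of r0, col_frac of c0)
    tilt: float = 0.0  # radians, positive tilts the top toward the image center


@dataclass(frozen=True)
class ConsolidationSpec:
    center: tuple[float, float]  # fractional (row, col)
    radius: float = 0.05  # fraction of min(r0, c0)
    intensity: float = 0.65


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one phantom; every field has a sane default."""

    image_size: tuple[int, int] = (512, 512)
    lungs: tuple[LungSpec, LungSpec] = (
        LungSpec(center=(0.47, 0.30), semi_axes=(0.30, 0.165), tilt=0.08),
        LungSpec(center=(0.47, 0.70), semi_axes=(0.30, 0.165), tilt=-0.08),
    )
    rib_count: int = 5
    vascular_amp: float = 0.12  # hilar vascular-marking brightness, fading peripherally
    texture_amp: float = 0.05  # correlated vascular texture inside the lungs
    texture_scale: float = 0.012  # texture correlation length, fraction of min(r0, c0)
    clavicle: bool = True
    diaphragm_dome_height: float = 0.50  # dome apex at center_row + this * semi_row
    noise_sd: float = 0.02  # additive Gaussian noise, fraction of dynamic range
    consolidation: ConsolidationSpec | None = None
    variant: str = "standard"
    background_border: float = 0.12  # pad fraction of min(r0, c0) for mobile variants
    glyph_blocks: int = 3
    seed: int = 0
    # intensities (display polarity: bright bone, dark air)
    body_intensity: float = 0.60
    lung_intensity: float = 0.25
    mediastinum_amp: float = 0.28
    rib_contrast: float = 0.10
    clavicle_contrast: float = 0.15
    abdomen_intensity: float = 0.72
    border_intensity: float = 0.05
    glyph_intensity: float = 0.92

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise PhantomConfigError(f"unknown variant {self.variant!r}")
        r0, c0 = self.image_size
        if r0 < 64 or c0 < 64:
            raise PhantomConfigError("phantom must be at least 64x64")
        for lung in self.lungs:
            (cr, cc), (sr, sc) = lung.center, lung.semi_axes
            if not (cr - sr > 0.02 and cr + sr < 0.98 and cc - sc > 0.02 and cc + sc < 0.98):
                raise PhantomConfigError("lung ellipse extends outside the chest frame")
        for name in (
            "body_intensity",
            "lung_intensity",
            "abdomen_intensity",
            "border_intensity",
            "glyph_intensity",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise PhantomConfigError(f"{name} outside [0, 1]")
        if not 0.0 <= self.noise_sd < 0.5:
            raise PhantomConfigError("noise_sd outside [0, 0.5)")


def _ellipse_mask(shape: tuple[int, int], lung: LungSpec) -> np.ndarray:
    r0, c0 = shape
    rr, cc = np.mgrid[0:r0, 0:c0].astype(np.float64)
    cy, cx = lung.center[0] * r0, lung.center[1] * c0
    sr, sc = lung.semi_axes[0] * r0, lung.semi_axes[1] * c0
    dr, dc = rr - cy, cc - cx
    cos_t, sin_t = np.cos(lung.tilt), np.sin(lung.tilt)
    u = cos_t * dc + sin_t * dr
    v = -sin_t * dc + cos_t * dr
    return (u / sc) ** 2 + (v / sr) ** 2 <= 1.0


def _dome_row(shape: tuple[int, int], lung: LungSpec, dome_height: float) -> np.ndarray:
    """Row of the diaphragm dome for each column (dome is convex upward)."""
    r0, c0 = shape
    cols = np.arange(c0, dtype=np.float64)
    cy, cx = lung.center[0] * r0, lung.center[1] * c0
    sr, sc = lung.semi_axes[0] * r0, lung.semi_axes[1] * c0
    apex = cy + dome_height * sr
    return apex + 0.35 * sr * ((cols - cx) / sc) ** 2


def _lung_regions(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(truth mask, full-ellipse union, below-dome-but-in-ellipse region)."""
    shape = spec.image_size
    rr = np.arange(shape[0], dtype=np.float64)[:, None]
    truth = np.zeros(shape, dtype=bool)
    ellipses = np.zeros(shape, dtype=bool)
    below = np.zeros(shape, dtype=bool)
    per_lung = []
    for lung in spec.lungs:
        ell = _ellipse_mask(shape, lung)
        dome = _dome_row(shape, lung, spec.diaphragm_dome_height)[None, :]
        above = rr <= dome
        per_lung.append(ell & above)
        truth |= ell & above
        ellipses |= ell
        below |= ell & ~above
    if (per_lung[0] & per_lung[1]).any():
        raise PhantomConfigError("left and right lung regions overlap")
    return truth, ellipses, below


def make_phantom(spec: PhantomSpec | None = None) -> tuple[Radiograph, np.ndarray]:
    """Render a phantom and its exact ground-truth lung mask.

    The returned radiograph is in the requested machine variant; the ground
    truth is always in standard-frame coordinates for the ``standard``
    variant and in the padded frame (lungs unchanged) for mobile variants.
    Deterministic for a fixed spec (including seed).
    """
    spec = spec or PhantomSpec()
    r0, c0 = spec.image_size
    rng = np.random.default_rng(spec.seed)
    img = np.full((r0, c0), spec.body_intensity, dtype=np.float64)

    # bright mediastinum / spine band: smooth Gaussian column profile, with a
    # vertical ramp emulating the narrower, less radiopaque superior
    # mediastinum (tracheal air column) near the apex
    cols = np.arange(c0, dtype=np.float64)
    band = spec.mediastinum_amp * np.exp(-0.5 * ((cols - 0.5 * c0) / (0.07 * c0)) ** 2)
    rows = np.arange(r0, dtype=np.float64)
    row_profile = 0.45 + 0.55 * np.clip(rows / (0.30 * r0), 0.0, 1.0)
    img += row_profile[:, None] * band[None, :]

    truth, ellipses, below_dome = _lung_regions(spec)
    img[ellipses] = spec.lung_intensity

    # vascular markings: brightness radiating from each hilum (medial,
    # mid-height), fading toward the lung periphery — gives radiographs their
    # continuous in-lung intensity distribution
    if spec.vascular_amp > 0:
        cc_grid = np.arange(c0, dtype=np.float64)[None, :]
        rr_grid = np.arange(r0, dtype=np.float64)[:, None]
        for lung in spec.lungs:
            cy, cx = lung.center[0] * r0, lung.center[1] * c0
            sr, sc = lung.semi_axes[0] * r0, lung.semi_axes[1] * c0
            medial = 1.0 if lung.center[1] < 0.5 else -1.0
            hr, hc = cy, cx + medial * 0.55 * sc
            d2 = ((rr_grid - hr) / (1.1 * sr)) ** 2 + ((cc_grid - hc) / (1.1 * sc)) ** 2
            ell = _ellipse_mask((r0, c0), lung)
            img[ell] += spec.vascular_amp * np.exp(-d2)[ell]

    # branching-vessel texture: band-limited noise spread through the lung
    # fields, so the in-lung intensity distribution is a continuum rather
    # than a flat level
    if spec.texture_amp > 0:
        from scipy import ndimage as ndi

        tex_rng = np.random.default_rng(spec.seed + 7919)
        sigma_tex = max(2.0, spec.texture_scale * min(r0, c0))
        tex = ndi.gaussian_filter(tex_rng.normal(size=(r0, c0)), sigma_tex)
        tex /= max(tex.std(), 1e-12)
        img[ellipses] += spec.texture_amp * tex[ellipses]

    # parabolic rib bands of limited contrast, crossing each lung
    rr = np.arange(r0, dtype=np.float64)[:, None]
    for lung in spec.lungs:
        cy, cx = lung.center[0] * r0, lung.center[1] * c0
        sr, sc = lung.semi_axes[0] * r0, lung.semi_axes[1] * c0
        for k in range(spec.rib_count):
            frac = (k + 0.5) / spec.rib_count
            center_row = cy - sr + 2.0 * sr * frac
            curve = center_row + 0.18 * sr * ((cols[None, :] - cx) / sc) ** 2
            band_mask = np.abs(rr - curve) <= max(2.0, 0.012 * r0)
            img[band_mask & ellipses] += spec.rib_contrast

    # diaphragm: bright abdomen below the domes
    img[below_dome] = spec.abdomen_intensity

    # clavicle bands near the apex, one per side, broad and slightly slanted;
    # their contrast fades toward the midline where the real clavicle shadow
    # is lost in the mediastinum brightness
    if spec.clavicle:
        midline_fade = 1.0 - np.exp(-0.5 * ((cols[None, :] - 0.5 * c0) / (0.08 * c0)) ** 2)
        for sign, lung in zip((1.0, -1.0), spec.lungs):
            cx = lung.center[1] * c0
            half_span = 0.19 * c0
            row0 = 0.105 * r0
            slope = -sign * 0.04  # rises toward the shoulder
            curve = row0 + slope * (cols[None, :] - cx)
            in_cols = np.abs(cols[None, :] - cx) <= half_span
            band_mask = (np.abs(rr - curve) <= 0.014 * r0) & in_cols
            img += np.where(band_mask, spec.clavicle_contrast * midline_fade, 0.0)

    if spec.consolidation is not None:
        blob = spec.consolidation
        cy, cx = blob.center[0] * r0, blob.center[1] * c0
        rad = blob.radius * min(r0, c0)
        cc_grid = np.arange(c0, dtype=np.float64)[None, :]
        disk_mask = (rr - cy) ** 2 + (cc_grid - cx) ** 2 <= rad * rad
        img[disk_mask & ellipses] = blob.intensity

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    radiograph = Radiograph(pixels=img, profile="standard", source_bit_depth=16)
    if spec.variant == "standard":
        return radiograph, truth
    padded = apply_variant(radiograph, spec)
    pad = _pad_width(spec)
    padded_truth = np.zeros(padded.pixels.shape, dtype=bool)
    padded_truth[pad : pad + r0, pad : pad + c0] = truth
    return padded, padded_truth


def _pad_width(spec: PhantomSpec) -> int:
    return int(round(spec.background_border * min(spec.image_size)))


def _glyph_layer(spec: PhantomSpec, padded_shape: tuple[int, int], pad: int) -> np.ndarray:
    """Bright text-like rectangles inside the border ring, outside the chest."""
    rng = np.random.default_rng(spec.seed + 104729)
    layer = np.zeros(padded_shape, dtype=bool)
    pr, pc = padded_shape
    gh = max(4, int(0.30 * pad))
    gw = max(10, int(0.09 * pc))
    # slots cycle over the four ring sides
    slots = []
    for frac in (0.15, 0.45, 0.75):
        slots.append(("top", frac))
        slots.append(("bottom", frac))
        slots.append(("left", frac))
        slots.append(("right", frac))
    margin = max(1, (pad - gh) // 2)  # keep glyphs centered in the ring,
    # clear of both the frame edge and the chest area
    for i in range(spec.glyph_blocks):
        side, frac = slots[i % len(slots)]
        jitter = int(rng.integers(0, max(1, margin // 3)))
        if side in ("top", "bottom"):
            r_start = (margin + jitter) if side == "top" else (pr - pad + margin + jitter)
            c_start = int(frac * (pc - gw))
            layer[r_start : r_start + gh, c_start : c_start + gw] = True
        else:
            # side glyphs are rotated (reading along the border)
            c_start = (margin + jitter) if side == "left" else (pc - pad + margin + jitter)
            r_start = int(frac * (pr - gw))
            layer[r_start : r_start + gw, c_start : c_start + gh] = True
    return layer


def apply_variant(img: Radiograph, spec: PhantomSpec, return_layers: bool = False):
    """Wrap a standard-profile phantom in the requested machine variant.

    ``standard`` returns the input unchanged; ``background`` pads a dark
    detector border with ``glyph_blocks`` bright text-like rectangles outside
    the chest; ``inverted_background`` additionally inverts the intensities.
    """
    if spec.variant == "standard":
        out = replace(img, pixels=img.pixels.copy())
        return (out, np.zeros(img.pixels.shape, dtype=bool)) if return_layers else out
    pad = _pad_width(spec)
    r0, c0 = img.pixels.shape
    canvas = np.full((r0 + 2 * pad, c0 + 2 * pad), spec.border_intensity, dtype=np.float64)
    canvas[pad : pad + r0, pad : pad + c0] = img.pixels
    glyphs = _glyph_layer(spec, canvas.shape, pad)
    canvas[glyphs] = spec.glyph_intensity
    profile = "background"
    if spec.variant == "inverted_background":
        canvas = 1.0 - canvas
        profile = "inverted_background"
    out = Radiograph(pixels=canvas, profile=profile, source_bit_depth=img.source_bit_depth)
    return (out, glyphs) if return_layers else out


def chest_bbox(spec: PhantomSpec) -> tuple[int, int, int, int]:
    """Bounding box of the chest (the un-padded frame) in variant coordinates."""
    r0, c0 = spec.image_size
    if spec.variant == "standard":
        return (0, r0, 0, c0)
    pad = _pad_width(spec)
    return (pad, pad + r0, pad, pad + c0)


def write_fixture_set(
    out_dir: str | Path,
    n: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    dicom: bool = False,
) -> dict:
    """Write n phantom/mask pairs plus a YAML manifest; returns the manifest.

    Case i uses ``seed + i``; regenerating from the manifest reproduces the
    files bit for bit. Images are 16-bit PNG (plus an optional minimal DICOM
    twin), masks 8-bit 0/255 PNG.
    """
    base_spec = base_spec or PhantomSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases = []
    for i in range(n):
        spec = replace(base_spec, seed=seed + i)
        img, truth = make_phantom(spec)
        image_name = f"phantom_{i:03d}.png"
        mask_name = f"phantom_{i:03d}_mask.png"
        lio.save_image_png16(img.pixels, out_dir / image_name)
        lio.save_mask_png(truth, out_dir / mask_name)
        case = {
            "image": image_name,
            "truth": mask_name,
            "seed": int(spec.seed),
            "variant": spec.variant,
        }
        if dicom:
            dicom_name = f"phantom_{i:03d}.dcm"
            lio.write_dicom(img.pixels, out_dir / dicom_name)
            case["dicom"] = dicom_name
        cases.append(case)
    manifest = {"n": n, "base_seed": int(seed), "variant": base_spec.variant, "cases": cases}
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
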