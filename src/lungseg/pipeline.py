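"""End-to-end orchestration of the segmentation method.

Flow: standardize (polarity / crop / contrast) -> resize to the outline
working resolution (512x512) -> seven oriented Gaussian-derivative responses
-> per-orientation automatic threshold + binarization -> per-orientation rule
cleanup -> combine and prune into L_outline -> resize to the fill/refine
resolution (256x256) -> HFEF + Otsu + convex hull fill into L_mask -> FCM
refinement into L_final -> nearest-neighbor upsampling back into the input
frame.

Resampling policy: area-average (anti-aliased bilinear) for intensities,
2x2 max-pooling for the outline (thin borders must survive downsampling),
nearest neighbor for final masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize

from lungseg import io as lio
from lungseg import metrics as lmetrics
from lungseg.auto_threshold import binarize, select_threshold
from lungseg.fcm_refine import refine
from lungseg.gaussian_bank import BANK_THETAS, respond_bank
from lungseg.mask_fill import EmptyOutlineError, fill_outline
from lungseg.outline_rules import RuleConfig, clean_response, combine_and_prune
from lungseg.preprocess import Radiograph, standardize


class PipelineError(RuntimeError):
    """Pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Every constant of the method, with the working defaults."""

    profile: str = "auto"
    gd_sigma: float = 3.0
    gd_thetas: tuple = BANK_THETAS
    # responses are expressed on a 12-bit intensity scale before the
    # integer-rounding threshold histogram is built
    response_scale: float = 4095.0
    thresh_peak_lo: float = 3.0
    thresh_peak_hi: float = 8.0
    thresh_fallback_pct: float = 98.0
    gd_size: int = 512
    fill_fcm_size: int = 256
    rules: RuleConfig = field(default_factory=RuleConfig)
    hfef_k1: float = 0.5
    hfef_k2: float = 1.5
    hfef_d0_frac: float = 0.25
    blur_size: int = 32
    blur_sigma: float = 10.0
    fill_selem_frac: float = 0.02
    fill_min_region_frac: float = 0.01
    fcm_n: int = 8
    fcm_m: float = 2.0
    fcm_tol: float = 1e-4
    fcm_max_iter: int = 200
    fcm_seed: int = 0
    refine_band: tuple = (0.4, 0.6)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        rules = RuleConfig(**raw.pop("rules", {}))
        cfg = cls(rules=rules, **{k: v for k, v in raw.items()})
        cfg.gd_thetas = tuple(cfg.gd_thetas)
        cfg.refine_band = tuple(cfg.refine_band)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["gd_thetas"] = list(self.gd_thetas)
        raw["refine_band"] = list(self.refine_band)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class PipelineResult:
    """Masks and intermediates from one run.

    ``l_final`` is in the input frame; ``l_outline`` (gd_size grid),
    ``l_mask`` and ``l_final_work`` (fill_fcm_size grid) are at working
    resolutions within the cropped frame.
    """

    l_outline: np.ndarray
    l_mask: np.ndarray
    l_final: np.ndarray
    l_final_work: np.ndarray
    bbox: tuple[int, int, int, int]
    input_shape: tuple[int, int]
    thresholds: list
    intermediates: dict
    log: list


def _resize_intensity(img: np.ndarray, size: int) -> np.ndarray:
    return resize(img, (size, size), order=1, mode="edge", anti_aliasing=True)


def _maxpool_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Downsample a binary outline, preserving thin structures (max pooling)."""
    r, c = mask.shape
    if r == c and r % size == 0:
        f = r // size
        return mask.reshape(size, f, size, f).any(axis=(1, 3))
    # non-integer factor: any-coverage via block sums on the resized float grid
    return resize(mask.astype(float), (size, size), order=1, mode="edge", anti_aliasing=False) > 0.0


def _upsample_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return resize(mask.astype(float), shape, order=0, mode="edge", anti_aliasing=False) > 0.5


def run_one(image, config: PipelineConfig | None = None, spine_axis_fn=None) -> PipelineResult:
    """Segment one radiograph (path or :class:`Radiograph`).

    ``spine_axis_fn`` is a disabled-by-default hook: if provided, it is
    called with the outline-resolution working image and its result is
    logged. No stage consumes it — the rules operate on image-width
    fractions — but the hook keeps a place for spine-axis estimation.
    """
    config = config or PipelineConfig()
    log: list = []

    if isinstance(image, (str, Path)):
        try:
            img = lio.load_image(image, profile=config.profile)
        except Exception as exc:  # unreadable / corrupt file
            raise PipelineError("load", str(exc)) from exc
    elif isinstance(image, Radiograph):
        img = image
    else:
        raise PipelineError("load", f"unsupported input type {type(image).__name__}")
    input_shape = (img.r0, img.c0)

    try:
        std, record = standardize(img, profile=config.profile)
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc
    log.append({"stage": "preprocess", **record})
    bbox = record["bbox"]

    # --- estimated lung outline at gd_size ---
    work = _resize_intensity(std.pixels, config.gd_size)
    if spine_axis_fn is not None:
        log.append({"stage": "spine_axis", "result": spine_axis_fn(work)})
    responses = respond_bank(work, sigma=config.gd_sigma, thetas=config.gd_thetas)
    thresholds = []
    cleaned = []
    for resp in responses:
        scaled = resp.values * config.response_scale
        t = select_threshold(
            scaled,
            lo=config.thresh_peak_lo,
            hi=config.thresh_peak_hi,
            fallback_pct=config.thresh_fallback_pct,
        )
        thresholds.append(t)
        mask = binarize(scaled, t)
        cleaned.append(clean_response(mask, config.rules))
        log.append(
            {
                "stage": "threshold",
                "theta": resp.theta,
                "value": t.value,
                "fallback": t.fallback,
                "degenerate": t.degenerate,
            }
        )
    l_outline = combine_and_prune(cleaned, config.rules)
    if not l_outline.any():
        raise PipelineError("outline", "estimated lung outline is empty")
    log.append({"stage": "outline", "pixels": int(l_outline.sum())})

    # --- fill at fill_fcm_size ---
    small = _resize_intensity(std.pixels, config.fill_fcm_size)
    outline_small = _maxpool_mask(l_outline, config.fill_fcm_size)
    try:
        fill = fill_outline(
            small,
            outline_small,
            k1=config.hfef_k1,
            k2=config.hfef_k2,
            d0_frac=config.hfef_d0_frac,
            blur_size=config.blur_size,
            blur_sigma=config.blur_sigma,
            selem_frac=config.fill_selem_frac,
            min_region_frac=config.fill_min_region_frac,
        )
    except EmptyOutlineError as exc:
        raise PipelineError("fill", str(exc)) from exc
    if not fill.l_mask.any():
        raise PipelineError("fill", "estimated lung mask is empty")
    log.append({"stage": "fill", "pixels": int(fill.l_mask.sum())})

    # --- FCM refinement ---
    try:
        clusters = refine(
            small,
            fill.l_mask,
            n=config.fcm_n,
            m=config.fcm_m,
            tol=config.fcm_tol,
            max_iter=config.fcm_max_iter,
            seed=config.fcm_seed,
            band=config.refine_band,
        )
    except ValueError as exc:
        raise PipelineError("fcm", str(exc)) from exc
    l_final_work = clusters.l_final
    log.append({"stage": "fcm", "pixels": int(l_final_work.sum())})

    # --- map back into the input frame ---
    crop_shape = (bbox[1] - bbox[0], bbox[3] - bbox[2])
    in_crop = _upsample_mask(l_final_work, crop_shape)
    l_final = np.zeros(input_shape, dtype=bool)
    l_final[bbox[0] : bbox[1], bbox[2] : bbox[3]] = in_crop

    return PipelineResult(
        l_outline=l_outline,
        l_mask=fill.l_mask,
        l_final=l_final,
        l_final_work=l_final_work,
        bbox=bbox,
        input_shape=input_shape,
        thresholds=thresholds,
        intermediates={
            "responses": responses,
            "cleaned": cleaned,
            "fill": fill,
            "clusters": clusters,
        },
        log=log,
    )


def run_batch(manifest, config: PipelineConfig | None = None, base_dir: str | Path | None = None):
    """Segment a batch described by a manifest; score cases that carry truth.

    ``manifest`` is a path to a YAML file (``cases: [{image, truth?}, ...]``)
    or an equivalent dict. Failures are recorded per case, not fatal. Returns
    a ``(table, summary)`` pair of DataFrames (summary is None when no case
    has a ground truth).
    """
    config = config or PipelineConfig()
    if isinstance(manifest, (str, Path)):
        base_dir = base_dir or Path(manifest).parent
        with open(manifest) as fh:
            manifest = yaml.safe_load(fh)
    base_dir = Path(base_dir) if base_dir is not None else Path(".")
    cases = manifest.get("cases", [])
    if not cases:
        raise ValueError("empty manifest")
    rows = []
    measure_sets = []
    for i, case in enumerate(cases):
        row: dict = {"case": i, "image": str(case["image"])}
        try:
            result = run_one(base_dir / case["image"], config)
            row["status"] = "ok"
            row["mask_pixels"] = int(result.l_final.sum())
            if case.get("truth"):
                truth = lio.load_mask(base_dir / case["truth"])
                ms = lmetrics.evaluate(result.l_final, truth)
                measure_sets.append(ms)
                row.update(ms.as_dict())
        except PipelineError as exc:
            row["status"] = f"failed:{exc.stage}"
        rows.append(row)
    table = pd.DataFrame(rows)
    summary = lmetrics.summarize(measure_sets) if measure_sets else None
    return table, summary
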