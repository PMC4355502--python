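"""Rule-based cleanup of thresholded responses and the combined lung outline.

Five rule groups, applied per orientation mask in this order: border
cleaning, small-region removal, clavicle elimination, sides'-artifact
elimination, body-artifact elimination. The seven cleaned masks are then
OR-combined and small laterally-placed fragments are pruned relative to the
largest region, giving the estimated lung outline L_outline.

Every rule is a pure component filter (8-connected): it can only delete whole
connected components, never add pixels. Comparisons follow the rule wording
exactly — "less than" is strict, "at most"/"at least" are inclusive — and
"located between X% and Y%" means every pixel of the component lies inside
the band. Radiological convention: the patient's right lung sits at low
column indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops


@dataclass
class RegionStats:
    """Extremal coordinates and area of one connected component."""

    area: int
    row_min: int
    row_max: int
    col_min: int
    col_max: int
    touches_border: bool

    @property
    def width(self) -> int:
        return self.col_max - self.col_min + 1


@dataclass
class RuleConfig:
    """All rule fractions, relative to image height r0, width c0 or area r0*c0."""

    small_region: float = 0.005  # remove components with area < this * image size
    clav_row_band: float = 0.35  # component confined to rows [0, band*r0)
    clav_row_min: float = 0.20  # top row at most this * r0
    clav_width: float = 0.15  # width at least this * c0
    clav_right_col_min: float = 0.25  # right case: col_min <= this * c0
    clav_left_col_max: float = 0.75  # left case: col_max >= this * c0
    side_width: float = 0.15  # width at most this * c0
    side_right_col_min: float = 0.05
    side_left_col_max: float = 0.85
    body_row_min: float = 0.25
    body_row_max: float = 0.90
    body_area: float = 0.025  # area at least this * image size
    body_right_col_min: float = 0.05
    body_left_col_max: float = 0.95
    prune_area: float = 0.15  # area < this * A_max
    prune_right_col_max: float = 0.20
    prune_left_col_min: float = 0.80

    def __post_init__(self) -> None:
        for name, val in vars(self).items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"rule fraction {name}={val} outside [0, 1]")


def region_stats(mask: np.ndarray) -> list[tuple[np.ndarray, RegionStats]]:
    """8-connected components with their pixel sets and extremal stats."""
    lab = label(mask, connectivity=2)
    r0, c0 = mask.shape
    out = []
    for reg in regionprops(lab):
        a0, b0, a1, b1 = reg.bbox
        stats = RegionStats(
            area=int(reg.area),
            row_min=a0,
            row_max=a1 - 1,
            col_min=b0,
            col_max=b1 - 1,
            touches_border=(a0 == 0 or b0 == 0 or a1 == r0 or b1 == c0),
        )
        out.append((lab == reg.label, stats))
    return out


def _filter_components(mask: np.ndarray, remove) -> np.ndarray:
    out = np.zeros_like(mask, dtype=bool)
    for comp, stats in region_stats(mask):
        if not remove(stats):
            out |= comp
    return out


def remove_border_connected(mask: np.ndarray) -> np.ndarray:
    """Delete every component that touches any image edge."""
    return _filter_components(mask, lambda s: s.touches_border)


def remove_small(mask: np.ndarray, frac: float = 0.005) -> np.ndarray:
    """Delete components with area strictly below ``frac`` of the image size."""
    size = mask.shape[0] * mask.shape[1]
    return _filter_components(mask, lambda s: s.area < frac * size)


def eliminate_clavicle(mask: np.ndarray, config: RuleConfig | None = None) -> np.ndarray:
    """Remove broad bands near the top of either lung field (clavicles)."""
    cfg = config or RuleConfig()
    r0, c0 = mask.shape

    def remove(s: RegionStats) -> bool:
        in_top_band = s.row_max < cfg.clav_row_band * r0
        near_top = s.row_min <= cfg.clav_row_min * r0
        broad = s.width >= cfg.clav_width * c0
        right_case = s.col_max < 0.5 * c0 and s.col_min <= cfg.clav_right_col_min * c0
        left_case = s.col_min >= 0.5 * c0 and s.col_max >= cfg.clav_left_col_max * c0
        return in_top_band and near_top and broad and (right_case or left_case)

    return _filter_components(mask, remove)


def eliminate_side_artifacts(mask: np.ndarray, config: RuleConfig | None = None) -> np.ndarray:
    """Remove narrow slivers hugging the left or right image margin."""
    cfg = config or RuleConfig()
    _, c0 = mask.shape

    def remove(s: RegionStats) -> bool:
        narrow = s.width <= cfg.side_width * c0
        right_case = s.col_min <= cfg.side_right_col_min * c0
        left_case = s.col_max >= cfg.side_left_col_max * c0
        return narrow and (right_case or left_case)

    return _filter_components(mask, remove)


def eliminate_body_artifacts(mask: np.ndarray, config: RuleConfig | None = None) -> np.ndarray:
    """Remove large lateral structures reaching the bottom of the frame.

    These are body-contour shadows that are not border-connected but sit very
    close to the bottom margin; the area floor protects hemidiaphragm arcs,
    which do not extend to the extreme side columns.
    """
    cfg = config or RuleConfig()
    r0, c0 = mask.shape
    size = r0 * c0

    def remove(s: RegionStats) -> bool:
        starts_low = s.row_min >= cfg.body_row_min * r0
        reaches_bottom = s.row_max >= cfg.body_row_max * r0
        big = s.area >= cfg.body_area * size
        right_case = s.col_min <= cfg.body_right_col_min * c0
        left_case = s.col_max >= cfg.body_left_col_max * c0
        return starts_low and reaches_bottom and big and (right_case or left_case)

    return _filter_components(mask, remove)


def clean_response(mask: np.ndarray, config: RuleConfig | None = None) -> np.ndarray:
    """Full per-orientation cleanup chain, in the prescribed order."""
    cfg = config or RuleConfig()
    out = remove_border_connected(mask)
    out = remove_small(out, cfg.small_region)
    out = eliminate_clavicle(out, cfg)
    out = eliminate_side_artifacts(out, cfg)
    out = eliminate_body_artifacts(out, cfg)
    return out


def combine_and_prune(masks, config: RuleConfig | None = None) -> np.ndarray:
    """OR the cleaned orientation masks and prune small lateral fragments.

    After combining, any component with area strictly below ``prune_area`` of
    the largest component's area A_max *and* confined to the outer column
    bands (col_max < 0.2*c0 or col_min > 0.8*c0) is discarded.
    """
    cfg = config or RuleConfig()
    masks = list(masks)
    if not masks:
        raise ValueError("no masks to combine")
    combined = np.zeros_like(masks[0], dtype=bool)
    for m in masks:
        if m.shape != combined.shape:
            raise ValueError("masks must share a common shape")
        combined |= m.astype(bool)
    if not combined.any():
        return combined
    comps = region_stats(combined)
    a_max = max(s.area for _, s in comps)
    _, c0 = combined.shape
    out = np.zeros_like(combined)
    for comp, s in comps:
        small = s.area < cfg.prune_area * a_max
        lateral = s.col_max < cfg.prune_right_col_max * c0 or s.col_min > cfg.prune_left_col_min * c0
        if not (small and lateral):
            out |= comp
    return out
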