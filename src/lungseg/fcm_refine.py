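"""Fuzzy c-means refinement of the estimated lung mask.

The estimated mask L_mask is mapped onto the pre-processed image (background
zeroed) and the resulting I_mask is clustered into n=8 intensity clusters
with standard FCM (fuzzifier m=2, scalar Euclidean distance). Hard cluster
images I_c1..I_c8 are ordered by ascending centroid, so I_c1 captures the
zeroed background. The combination rules:

* I_c5 (mid intensities: the shell between dark lung cores and bright rims)
  is closed, hole-filled, reduced to its two largest components and dilated
  once -> the "minimum lung region" gate, processed_c5.
* I_c2..I_c4 (dark lung cores) are unioned and gated by processed_c5
  -> I_c234.
* I_c6 is eroded once; then eroded-c6, c7 and c8 (bright rims) have every
  pixel in the central 40-60% column band removed (sternum / spine shadow)
  and are unioned -> I_c678.
* L_final = union of the three, hole-filled, two largest components kept,
  one opening to smooth, optionally upsampled back to the original frame.

All randomness (centroid jitter) is controlled by a seed; the whole stage is
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk
from skimage.transform import resize


@dataclass
class FcmModel:
    n_clusters: int
    m: float
    centroids: np.ndarray  # sorted ascending
    memberships: np.ndarray  # (n_pixels, n_clusters), rows sum to 1
    objective_trace: np.ndarray
    seed: int
    converged: bool


@dataclass
class ClusterImages:
    """Hard cluster images (ascending centroid order) and the combination steps."""

    images: list  # I_c1..I_cn as boolean arrays
    centroids: np.ndarray
    i_c234: np.ndarray | None = None
    i_c678: np.ndarray | None = None
    processed_c5: np.ndarray | None = None
    processed_c6: np.ndarray | None = None
    l_final: np.ndarray | None = None


def fcm(
    data: np.ndarray,
    n: int = 8,
    m: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
) -> FcmModel:
    """Standard fuzzy c-means on scalar intensities.

    Membership update ``u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))``, centroid
    update ``v_i = sum_k u_ik^m x_k / sum_k u_ik^m``; stops when the largest
    relative centroid shift drops below ``tol``. Initial centroids sit at
    evenly spaced quantiles of the *unique* data values with a small
    seed-controlled jitter, which keeps them distinct even when one value
    (e.g. a zeroed background) dominates the distribution.
    """
    x = np.asarray(data, dtype=np.float64).ravel()
    if n < 2:
        raise ValueError("need at least 2 clusters")
    uniq = np.unique(x)
    if uniq.size < n:
        raise ValueError(f"{n} clusters requested but only {uniq.size} distinct values")
    rng = np.random.default_rng(seed)
    span = uniq[-1] - uniq[0]
    q = (np.arange(n) + 0.5) / n
    v = np.quantile(uniq, q)
    v = v + rng.uniform(-1.0, 1.0, size=n) * span / (20.0 * n)
    v = np.clip(np.sort(v), uniq[0], uniq[-1])

    exponent = 2.0 / (m - 1.0)
    trace = []
    converged = False
    u = np.empty((x.size, n))
    for _ in range(max_iter):
        d = np.abs(x[:, None] - v[None, :])
        zero = d < 1e-12
        with np.errstate(divide="ignore"):
            w = d ** (-exponent)
        w[zero] = 0.0
        any_zero = zero.any(axis=1)
        u = np.where(any_zero[:, None], zero / np.maximum(zero.sum(axis=1)[:, None], 1), 0.0)
        ok = ~any_zero
        u[ok] = w[ok] / w[ok].sum(axis=1, keepdims=True)
        um = u**m
        trace.append(float((um * d * d).sum()))
        denom = um.sum(axis=0)
        v_new = np.where(denom > 0, um.T @ x / np.maximum(denom, 1e-300), v)
        shift = np.max(np.abs(v_new - v)) / max(span, 1e-12)
        v = v_new
        if shift < tol:
            converged = True
            break
    order = np.argsort(v)
    return FcmModel(
        n_clusters=n,
        m=m,
        centroids=v[order],
        memberships=u[:, order],
        objective_trace=np.asarray(trace),
        seed=seed,
        converged=converged,
    )


def harden_and_sort(model: FcmModel, shape: tuple[int, int]) -> ClusterImages:
    """Hard-assign pixels by maximum membership; ties go to the lower centroid.

    Cluster labels follow ascending centroid order (done in :func:`fcm`), so
    I_c1 holds the darkest pixels — the zeroed background of I_mask.
    """
    u = model.memberships
    # argmax returns the first (lowest-centroid) cluster on ties
    labels = np.argmax(u, axis=1).reshape(shape)
    images = [labels == k for k in range(model.n_clusters)]
    return ClusterImages(images=images, centroids=model.centroids.copy())


def process_c5(
    i_c5: np.ndarray,
    l_mask: np.ndarray | None = None,
    closing_frac: float = 0.06,
    dilation_radius: int = 1,
) -> np.ndarray:
    """Morphological gate from the fifth cluster: the minimum lung region.

    The mid-intensity cluster is spread through the lung fields as vessel /
    rib texture; a closing with a disk of radius ``closing_frac`` of the
    image width bridges the gaps between those structures (inter-rib spacing
    scale), then hole filling, two largest components, one dilation. An
    empty input falls back to ``l_mask`` (with a warning) so the gate never
    wipes out the refinement.
    """
    mask = np.asarray(i_c5, dtype=bool)
    if not mask.any():
        warnings.warn("process_c5: empty cluster, gating with L_mask instead")
        if l_mask is None:
            return mask.copy()
        return np.asarray(l_mask, dtype=bool).copy()
    radius = max(1, int(round(closing_frac * mask.shape[1])))
    out = ndi.binary_closing(mask, structure=disk(radius).astype(bool), border_value=0)
    out = ndi.binary_fill_holes(out)
    out = keep_largest(out, 2)
    return ndi.binary_dilation(out, structure=disk(dilation_radius).astype(bool))


def keep_largest(mask: np.ndarray, k: int) -> np.ndarray:
    """Keep the k largest 8-connected components."""
    lab, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n <= k:
        return mask.astype(bool)
    areas = np.bincount(lab.ravel())
    areas[0] = 0
    keep = np.argsort(areas)[-k:]
    return np.isin(lab, keep)


def gate_inner(
    i_c2: np.ndarray, i_c3: np.ndarray, i_c4: np.ndarray, processed_c5: np.ndarray
) -> np.ndarray:
    """I_c234: the dark lung cores, restricted to the minimum lung region."""
    return (np.asarray(i_c2, bool) | np.asarray(i_c3, bool) | np.asarray(i_c4, bool)) & np.asarray(
        processed_c5, bool
    )


def gate_outer(
    i_c6: np.ndarray,
    i_c7: np.ndarray,
    i_c8: np.ndarray,
    band: tuple[float, float] = (0.4, 0.6),
    erosion_radius: int = 1,
) -> np.ndarray:
    """I_c678: bright outer-lung detail, with the central column band removed.

    I_c6 is eroded once first; then every pixel whose column lies in
    ``[band[0]*c0, band[1]*c0]`` is discarded from each of the three masks
    before the union (drops sternum/spine-shadow pixels).
    """
    c6 = ndi.binary_erosion(np.asarray(i_c6, bool), structure=disk(erosion_radius).astype(bool))
    c0 = c6.shape[1]
    cols = np.arange(c0)
    in_band = (cols >= band[0] * c0) & (cols <= band[1] * c0)
    keep_cols = ~in_band[None, :]
    return (c6 & keep_cols) | (np.asarray(i_c7, bool) & keep_cols) | (
        np.asarray(i_c8, bool) & keep_cols
    )


def finalize(
    i_c234: np.ndarray,
    processed_c5: np.ndarray,
    i_c678: np.ndarray,
    l_mask: np.ndarray,
    out_shape: tuple[int, int] | None = None,
    opening_radius: int = 1,
    decline_frac: float = 0.5,
) -> np.ndarray:
    """Combine the cluster groups into the final lung mask L_final.

    Union, hole filling, two largest components, one opening; optionally
    nearest-neighbor upsampling to ``out_shape``. The refinement is meant to
    *trim* the estimated mask, so it is declined (L_mask returned, with a
    warning) when the combined evidence is degenerate: an empty union, or a
    refined mask smaller than ``decline_frac`` of the L_mask area — the
    latter signals that the intensity clusters failed to line up with the
    lung fields, and a collapsed mask would be worse than the unrefined one.
    """
    l_mask = np.asarray(l_mask, bool)
    union = np.asarray(i_c234, bool) | np.asarray(processed_c5, bool) | np.asarray(i_c678, bool)
    if not union.any():
        warnings.warn("finalize: empty refinement, falling back to L_mask")
        out = l_mask.copy()
        if out_shape is not None and out_shape != out.shape:
            out = resize(out.astype(float), out_shape, order=0, mode="edge", anti_aliasing=False) > 0.5
        return out
    out = ndi.binary_fill_holes(union)
    out = keep_largest(out, 2)
    out = ndi.binary_opening(out, structure=disk(opening_radius).astype(bool))
    if out.sum() < decline_frac * l_mask.sum():
        warnings.warn("finalize: refinement collapsed the mask, falling back to L_mask")
        out = l_mask.copy()
    if out_shape is not None and out_shape != out.shape:
        out = resize(out.astype(float), out_shape, order=0, mode="edge", anti_aliasing=False) > 0.5
    return out


def refine(
    img: np.ndarray,
    l_mask: np.ndarray,
    n: int = 8,
    m: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
    band: tuple[float, float] = (0.4, 0.6),
    out_shape: tuple[int, int] | None = None,
) -> ClusterImages:
    """Full refinement stage on a working-resolution image and mask."""
    if img.shape != l_mask.shape:
        raise ValueError("image and mask must share a shape")
    i_mask = np.where(np.asarray(l_mask, bool), np.asarray(img, dtype=np.float64), 0.0)
    model = fcm(i_mask.ravel(), n=n, m=m, tol=tol, max_iter=max_iter, seed=seed)
    clusters = harden_and_sort(model, img.shape)
    c = clusters.images
    # the minimum lung region cannot exceed the estimated mask: the closing
    # may bulge past the L_mask rim, so the gate is clipped back to it —
    # refinement only ever trims
    clusters.processed_c5 = process_c5(c[4], l_mask=l_mask) & np.asarray(l_mask, bool)
    clusters.i_c234 = gate_inner(c[1], c[2], c[3], clusters.processed_c5)
    clusters.i_c678 = gate_outer(c[5], c[6], c[7], band=band)
    clusters.l_final = finalize(
        clusters.i_c234, clusters.processed_c5, clusters.i_c678, l_mask, out_shape=out_shape
    )
    return clusters
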