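"""c-Fos positive cell counting and batch normalization.

Reproduces the counting-macro logic: maximum-intensity projection of the
five middle planes of a confocal z-stack, binarization, connected-component
segmentation filtered by area and circularity inside each region-of-interest
mask, and normalization of each culture's count by the mean of the control
group in the same batch and region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import filters, measure

# Default particle filters.  Circularity = 4*pi*A/P^2, capped at 1.0 (the
# theoretical maximum for a circle) before range filtering, matching the
# common particle-analysis convention for digitized discs.
DEFAULT_SIZE_RANGE = (30.0, 500.0)       # px^2
DEFAULT_CIRCULARITY_RANGE = (0.4, 1.0)


def max_project_mid_planes(stack: np.ndarray, n: int = 5) -> np.ndarray:
    """Maximum-intensity projection over the n planes centered on the stack
    midpoint.

    For a stack of depth z the selected 0-based planes are
    ``(z - n) // 2 .. (z - n) // 2 + n - 1`` (symmetric-as-possible for even
    leftovers).
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be z x H x W")
    z = stack.shape[0]
    if z < n:
        raise ValueError(f"stack has only {z} planes; {n} required")
    start = (z - n) // 2
    return stack[start:start + n].max(axis=0)


def circularity(area: float, perimeter: float) -> float:
    """4*pi*A/P^2, capped at 1.0; infinite for degenerate zero perimeter."""
    if perimeter <= 0:
        return np.inf
    return min(1.0, 4.0 * np.pi * area / perimeter ** 2)


def measure_blobs(binary: np.ndarray) -> pd.DataFrame:
    """Area and capped circularity of each 8-connected component."""
    lab = measure.label(binary, connectivity=2)
    rows = []
    for rp in measure.regionprops(lab):
        rows.append({
            "label": rp.label,
            "area": float(rp.area),
            "perimeter": float(rp.perimeter),
            "circularity": circularity(rp.area, rp.perimeter),
        })
    return pd.DataFrame(rows, columns=["label", "area", "perimeter", "circularity"])


def passes_filters(area: float, circ: float,
                   size_range=DEFAULT_SIZE_RANGE,
                   circularity_range=DEFAULT_CIRCULARITY_RANGE) -> bool:
    return (size_range[0] <= area <= size_range[1]
            and circularity_range[0] <= circ <= circularity_range[1])


def count_positive_cells(image: np.ndarray, mask: np.ndarray | None = None,
                         threshold_method: str = "otsu",
                         size_range=DEFAULT_SIZE_RANGE,
                         circularity_range=DEFAULT_CIRCULARITY_RANGE) -> int:
    """Count filtered connected components inside a region of interest.

    The image is binarized (Otsu threshold computed on the masked region by
    default, or a quantile via ``"quantile:0.95"``), 8-connected components
    inside the mask are labeled, and components whose area and capped
    circularity fall within the configured ranges are counted.
    """
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = image[mask]
    if threshold_method == "otsu":
        if np.ptp(vals) == 0:
            return 0  # flat region: nothing to segment
        thr = filters.threshold_otsu(vals)
    elif threshold_method.startswith("quantile:"):
        q = float(threshold_method.split(":", 1)[1])
        thr = np.quantile(vals, q)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    binary = (image > thr) & mask
    blobs = measure_blobs(binary)
    if blobs.empty:
        return 0
    keep = [passes_filters(a, c, size_range, circularity_range)
            for a, c in zip(blobs["area"], blobs["circularity"])]
    return int(np.sum(keep))


def count_stack(stack: np.ndarray, roi_masks: dict[str, np.ndarray],
                n_mid_planes: int = 5, **filter_kwargs) -> dict[str, int]:
    """Project the stack's middle planes and count per named ROI."""
    proj = max_project_mid_planes(stack, n=n_mid_planes)
    return {name: count_positive_cells(proj, m, **filter_kwargs)
            for name, m in roi_masks.items()}


def normalize_by_control_mean(table: pd.DataFrame,
                              control_label: str = "control") -> pd.DataFrame:
    """Normalize raw counts by the control-group mean per (batch, region).

    Adds a ``normalized_count`` column: raw count divided by the mean raw
    count of control cultures in the same batch and region.  Every
    (batch, region) stratum must contain at least one control culture with a
    positive mean.
    """
    req = {"culture_id", "batch_id", "group", "region", "raw_count"}
    if not req.issubset(table.columns):
        raise ValueError(f"count table must have columns {sorted(req)}")
    out = table.copy()
    ctrl = out[out["group"] == control_label]
    means = ctrl.groupby(["batch_id", "region"])["raw_count"].mean()
    strata = out.set_index(["batch_id", "region"]).index.unique()
    missing = [s for s in strata if s not in means.index]
    if missing:
        raise ValueError(f"strata without control cultures: {missing}")
    zero = means[means == 0]
    if len(zero):
        raise ValueError(f"control mean is zero in strata: {list(zero.index)}")
    denom = means.reindex(
        pd.MultiIndex.from_frame(out[["batch_id", "region"]])).to_numpy()
    out["normalized_count"] = out["raw_count"].to_numpy() / denom
    return out
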