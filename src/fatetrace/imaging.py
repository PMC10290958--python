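"""Nuclei dot counting: greyscale conversion, multi-Otsu background
removal, connected components, knee-point maximum-size gating and the
final count.

The maximum dot size is found on the ascending sorted component-size
curve as the point of maximum distance below the chord from first to
last point (a Kneedle-style knee).  The knee is only trusted when the
curve has a pronounced corner; otherwise — and always as a cap — a
hardcoded maximum applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_multiotsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentStats",
    "to_greyscale",
    "multi_otsu_mask",
    "connected_components",
    "elbow_max_size",
    "count_dots",
    "count_dots_pipeline",
]

DEFAULT_MIN_SIZE = 20
DEFAULT_MAX_SIZE = 2000.0

_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class ComponentStats:
    component_id: int
    size: int
    bbox: tuple
    centroid: tuple

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("component size must be >= 1")


def to_greyscale(image: np.ndarray) -> np.ndarray:
    """Luminance-weighted greyscale in [0, 1]."""
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        if img.shape[2] == 4:
            img = img[..., :3]
        if img.shape[2] != 3:
            raise ValueError("expected a 2-D or 3-channel image")
        grey = img.astype(float) @ _LUMA
    elif img.ndim == 2:
        grey = img.astype(float)
    else:
        raise ValueError("expected a 2-D or 3-channel image")
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        grey = grey / np.iinfo(np.asarray(image).dtype).max
    return np.clip(grey, 0.0, 1.0)


def multi_otsu_mask(image: np.ndarray, n_classes: int = 3, nbins: int = 256,
                    rule: str = "lowest") -> np.ndarray:
    """Foreground mask from multi-Otsu thresholds.

    ``rule='lowest'`` keeps everything above the lowest threshold
    (removes only the darkest, background class); ``rule='highest'``
    keeps only the brightest class.
    """
    if rule not in ("lowest", "highest"):
        raise ValueError(f"unknown rule {rule!r}")
    img = np.asarray(image, dtype=float)
    if np.unique(img).size < n_classes:
        raise ValueError(
            f"image has fewer than {n_classes} distinct intensity levels")
    thresholds = threshold_multiotsu(img, classes=n_classes, nbins=nbins)
    cut = thresholds[0] if rule == "lowest" else thresholds[-1]
    return img > cut


def connected_components(mask: np.ndarray) -> list[ComponentStats]:
    """8-connectivity component statistics; empty mask -> empty list."""
    lab = cc_label(np.asarray(mask, dtype=bool), connectivity=2)
    return [ComponentStats(component_id=p.label, size=int(p.area),
                           bbox=tuple(p.bbox), centroid=tuple(p.centroid))
            for p in regionprops(lab)]


def elbow_max_size(sizes, hard_max: float = DEFAULT_MAX_SIZE,
                   sensitivity: float = 0.3) -> float:
    """Maximum-size gate from the knee of the ascending sorted-size curve.

    The knee is the point of maximum distance below the chord from the
    first to the last point.  When fewer than 3 components are given, the
    curve is flat, or the corner is weaker than ``sensitivity`` (maximum
    deviation relative to the size range), the hardcoded maximum is used.
    The returned threshold never exceeds ``hard_max``.
    """
    sizes = np.sort(np.asarray(list(sizes), dtype=float))
    n = len(sizes)
    if n < 3:
        logger.info("fewer than 3 components; falling back to hard max")
        return float(hard_max)
    s0, s_end = sizes[0], sizes[-1]
    if s_end == s0:
        logger.info("all component sizes equal; falling back to hard max")
        return float(hard_max)
    i = np.arange(n)
    # signed area cross-product with the chord; negative = below chord.
    # the chord-length denominator is constant over i, so the argmax of
    # the perpendicular distance equals the argmax of |cross|.
    cross = (n - 1) * (sizes - s0) - (s_end - s0) * i
    below = -cross
    knee = int(np.argmax(below))
    deviation = below[knee] / ((n - 1) * (s_end - s0))
    if deviation < sensitivity:
        logger.info("no pronounced knee (deviation %.3f); using hard max",
                    deviation)
        return float(hard_max)
    return float(min(sizes[knee], hard_max))


def count_dots(components, min_size: float = DEFAULT_MIN_SIZE,
               max_size: float = DEFAULT_MAX_SIZE) -> int:
    """Number of components with min_size <= size <= max_size."""
    if min_size <= 0 or max_size <= 0:
        raise ValueError("size gates must be positive")
    if min_size >= max_size:
        raise ValueError("min_size must be < max_size")
    return sum(1 for c in components if min_size <= c.size <= max_size)


def count_dots_pipeline(image: np.ndarray,
                        min_size: float = DEFAULT_MIN_SIZE,
                        hard_max: float = DEFAULT_MAX_SIZE,
                        n_classes: int = 3, nbins: int = 256,
                        mask_rule: str = "lowest",
                        knee_sensitivity: float = 0.3) -> dict:
    """Full dot-counting pipeline; returns a JSON-serializable report."""
    grey = to_greyscale(image)
    if np.unique(grey).size < 2:
        return {"count": 0, "thresholds": [], "sizes": [],
                "max_size_used": float(hard_max), "note": "blank image"}
    thresholds = threshold_multiotsu(
        grey, classes=min(n_classes, np.unique(grey).size), nbins=nbins)
    cut = thresholds[0] if mask_rule == "lowest" else thresholds[-1]
    mask = grey > cut
    comps = connected_components(mask)
    sizes = [c.size for c in comps]
    gated = [s for s in sizes if s >= min_size]
    max_used = elbow_max_size(gated, hard_max=hard_max,
                              sensitivity=knee_sensitivity) \
        if len(gated) >= 3 else float(hard_max)
    count = count_dots(comps, min_size=min_size, max_size=max_used)
    return {
        "count": int(count),
        "thresholds": [float(t) for t in np.atleast_1d(thresholds)],
        "sizes": sorted(int(s) for s in sizes),
        "max_size_used": float(max_used),
    }
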