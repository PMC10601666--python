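"""Fluorescent cell detection and two-channel starter classification.

Cells are segmented per channel as connected components above a robust
intensity threshold (median + k * MAD-based sd), then filtered on area,
isoperimetric circularity, and SNR. A rabies-channel detection whose centroid
lies within a configurable distance of a helper-channel detection is called a
starter; unmatched rabies detections are presynaptic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

__all__ = [
    "DetectionParams",
    "Detection",
    "CellCall",
    "circularity",
    "detect_cells",
    "classify_starters",
]

MAD_SCALE = 1.4826  # consistency factor: MAD -> sd under normality


@dataclass(frozen=True)
class DetectionParams:
    """User-adjustable segmentation thresholds (size, roundness, intensity)."""

    min_area_px: int = 20
    max_area_px: int = 500
    min_circularity: float = 0.4
    min_snr: float = 3.0
    threshold_k: float = 5.0

    def __post_init__(self) -> None:
        if self.min_area_px >= self.max_area_px:
            raise ValueError(
                f"min_area_px ({self.min_area_px}) must be < max_area_px "
                f"({self.max_area_px})"
            )
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValueError("min_circularity must lie in [0, 1]")
        if self.min_snr <= 0:
            raise ValueError("min_snr must be > 0")


@dataclass(frozen=True)
class Detection:
    centroid: tuple[float, float]  # (x, y) = (column, row)
    area_px: int
    circularity: float
    snr: float
    mean_intensity: float
    channel: str  # "helper" | "rabies"


@dataclass
class CellCall:
    centroid: tuple[float, float]
    kind: str  # "starter" | "presynaptic" | "helper_only"
    region_id: int | None = None
    hemisphere: str | None = None


def circularity(area_px: float, perimeter_px: float) -> float:
    """Isoperimetric circularity 4*pi*A/P^2, clamped to 1 for an ideal disk."""
    if perimeter_px <= 0:
        raise ValueError(f"perimeter must be > 0, got {perimeter_px}")
    return min(1.0, 4.0 * math.pi * area_px / perimeter_px**2)


def detect_cells(
    image: np.ndarray,
    params: DetectionParams = DetectionParams(),
    channel: str = "rabies",
) -> list[Detection]:
    """Segment one channel into filtered cell detections.

    Returns detections sorted by descending mean intensity (ties broken by
    centroid), deterministic for a given image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if np.any(img < 0):
        raise ValueError("image contains negative pixels")

    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    threshold = med + params.threshold_k * MAD_SCALE * mad

    fg = img > threshold
    if not fg.any():
        return []

    bg_pixels = img[~fg]
    if bg_pixels.size:
        bg_med = float(np.median(bg_pixels))
        bg_sd = MAD_SCALE * float(np.median(np.abs(bg_pixels - bg_med)))
    else:
        bg_sd = 0.0

    labels = measure.label(fg, connectivity=2)
    detections: list[Detection] = []
    for prop in measure.regionprops(labels, intensity_image=img):
        area = int(prop.area)
        if not params.min_area_px <= area <= params.max_area_px:
            continue
        perim = float(prop.perimeter)
        if perim <= 0:
            continue
        circ = circularity(area, perim)
        if circ < params.min_circularity:
            continue
        mean_int = float(prop.intensity_mean)
        snr = mean_int / bg_sd if bg_sd > 0 else math.inf
        if snr < params.min_snr:
            continue
        cy, cx = prop.centroid_weighted
        detections.append(
            Detection(
                centroid=(float(cx), float(cy)),
                area_px=area,
                circularity=circ,
                snr=snr,
                mean_intensity=mean_int,
                channel=channel,
            )
        )
    detections.sort(key=lambda d: (-d.mean_intensity, d.centroid))
    return detections


def classify_starters(
    helper: list[Detection],
    rabies: list[Detection],
    max_dist_px: float = 5.0,
) -> list[CellCall]:
    """Pair rabies and helper centroids greedily by ascending distance.

    Matched pairs within *max_dist_px* become starters (at the rabies
    centroid); unmatched rabies cells are presynaptic; unmatched helper cells
    are helper_only. Matching is one-to-one and independent of input order.
    """
    if max_dist_px < 0:
        raise ValueError("max_dist_px must be >= 0")
    # canonical order so greedy tie-breaks don't depend on caller ordering
    helper = sorted(helper, key=lambda d: d.centroid)
    rabies = sorted(rabies, key=lambda d: d.centroid)

    candidates: list[tuple[float, int, int]] = []
    for ri, r in enumerate(rabies):
        for hi, h in enumerate(helper):
            d = math.dist(r.centroid, h.centroid)
            if d <= max_dist_px:
                candidates.append((d, ri, hi))
    candidates.sort()

    matched_r: set[int] = set()
    matched_h: set[int] = set()
    calls: list[CellCall] = []
    for d, ri, hi in candidates:
        if ri in matched_r or hi in matched_h:
            continue
        matched_r.add(ri)
        matched_h.add(hi)
        calls.append(CellCall(centroid=rabies[ri].centroid, kind="starter"))
    for ri, r in enumerate(rabies):
        if ri not in matched_r:
            calls.append(CellCall(centroid=r.centroid, kind="presynaptic"))
    for hi, h in enumerate(helper):
        if hi not in matched_h:
            calls.append(CellCall(centroid=h.centroid, kind="helper_only"))
    calls.sort(key=lambda c: (c.kind, c.centroid))
    return calls
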