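"""Landmark-based planar registration of section images to atlas slices.

A per-section affine transform is fit by least squares from user-supplied
matching point pairs, then used to carry cell calls into atlas pixel space,
where each call picks up its region label and hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import UNASSIGNED_ID, AtlasSlice
from .detection import CellCall

__all__ = [
    "LandmarkSet",
    "PlanarTransform",
    "DegenerateLandmarksError",
    "fit_affine",
    "assign_regions",
]


class DegenerateLandmarksError(ValueError):
    """Fewer than 3 landmark pairs, or image points collinear."""


@dataclass(frozen=True)
class LandmarkSet:
    pairs: tuple[tuple[tuple[float, float], tuple[float, float]], ...]
    section_id: str = ""
    ap_mm: float = 0.0

    @classmethod
    def from_arrays(cls, image_pts, atlas_pts, section_id="", ap_mm=0.0):
        image_pts = np.asarray(image_pts, dtype=float)
        atlas_pts = np.asarray(atlas_pts, dtype=float)
        if image_pts.shape != atlas_pts.shape or image_pts.ndim != 2:
            raise ValueError("image and atlas point arrays must have matching Nx2 shape")
        pairs = tuple(
            (tuple(ip), tuple(ap)) for ip, ap in zip(image_pts, atlas_pts)
        )
        return cls(pairs=pairs, section_id=section_id, ap_mm=ap_mm)

    @property
    def image_points(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=float)

    @property
    def atlas_points(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=float)


@dataclass(frozen=True)
class PlanarTransform:
    """2x3 affine mapping image (x, y) -> atlas (x, y)."""

    matrix: np.ndarray
    rms_residual_px: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("linear part of affine transform is singular")
        object.__setattr__(self, "matrix", m)

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "PlanarTransform":
        a = self.matrix[:, :2]
        t = self.matrix[:, 2]
        a_inv = np.linalg.inv(a)
        return PlanarTransform(
            matrix=np.hstack([a_inv, (-a_inv @ t)[:, None]]),
            rms_residual_px=self.rms_residual_px,
        )


def fit_affine(landmarks: LandmarkSet) -> PlanarTransform:
    """Least-squares affine minimizing atlas-space residuals.

    Exact interpolation with 3 non-collinear pairs; with more pairs the RMS
    residual is reported on the transform.
    """
    src = landmarks.image_points
    dst = landmarks.atlas_points
    if len(src) < 3:
        raise DegenerateLandmarksError(
            f"need >= 3 landmark pairs, got {len(src)}"
        )
    design = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateLandmarksError("image landmark points are collinear")
    coeffs, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = coeffs.T  # 2x3
    transform = PlanarTransform(matrix=matrix)
    residuals = transform.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return PlanarTransform(matrix=matrix, rms_residual_px=rms)


def assign_regions(
    calls: list[CellCall],
    transform: PlanarTransform,
    atlas_slice: AtlasSlice,
    section_side: str = "left",
) -> list[CellCall]:
    """Fill region_id and hemisphere for each call by nearest-pixel mask lookup.

    Calls mapping outside the mask bounds or onto background get
    ``region_id = UNASSIGNED_ID``. Points landing exactly on the midline
    column tie-break to *section_side*. Never drops or duplicates calls.
    """
    if section_side not in ("left", "right"):
        raise ValueError(f"section_side must be 'left' or 'right', got {section_side}")
    mask = atlas_slice.label_mask
    h, w = mask.shape
    out: list[CellCall] = []
    if calls:
        mapped = transform.apply([c.centroid for c in calls])
    else:
        mapped = np.empty((0, 2))
    for call, (ax, ay) in zip(calls, mapped):
        col = int(round(ax))
        row = int(round(ay))
        if 0 <= row < h and 0 <= col < w:
            region_id = int(mask[row, col])
        else:
            region_id = UNASSIGNED_ID
        if col < atlas_slice.midline_x:
            hemi = "left"
        elif col > atlas_slice.midline_x:
            hemi = "right"
        else:
            hemi = section_side
        out.append(
            CellCall(
                centroid=call.centroid,
                kind=call.kind,
                region_id=region_id,
                hemisphere=hemi,
            )
        )
    return out
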