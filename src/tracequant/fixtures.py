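"""Synthetic atlases, rendered two-channel sections, and dimorphic cohorts.

Everything downstream (detection, registration, quantification, statistics)
is exercised against data produced here, with ground truth emitted alongside:
cell truth tables for the imaging stages, expected per-region rates for the
cohort stages. All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .atlas import AtlasSlice, RegionAtlas, RegionNode
from .quantify import HemisphereSample

__all__ = [
    "TruthCell",
    "CohortSpec",
    "make_synthetic_atlas",
    "render_section",
    "place_cells_in_regions",
    "simulate_cohort",
    "match_to_truth",
]

CHANNELS = ("helper", "rabies", "both")


@dataclass(frozen=True)
class TruthCell:
    x: float
    y: float
    radius_px: float
    peak_intensity: float
    channel: str  # "helper" | "rabies" | "both"
    region_id: int
    is_starter: bool

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be > 0")
        if self.is_starter != (self.channel == "both"):
            raise ValueError("is_starter must hold exactly when channel is 'both'")


@dataclass(frozen=True)
class NoiseParams:
    background_mean: float = 100.0
    background_sd: float = 5.0
    psf_sigma_px: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of one simulated two-sex cohort.

    Each entry of *regions* is (region_id, base_pps, male_multiplier); female
    expected PPS is base_pps, male expected PPS is base_pps * male_multiplier.
    """

    regions: tuple[tuple[int, float, float], ...]
    n_male: int = 7
    n_female: int = 7
    starter_mean: float = 50.0
    starter_target_region: int = 1
    spill_fraction: float = 0.1
    noise: NoiseParams = NoiseParams()
    dispersion: float | None = None  # negative-binomial size; None = Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 1 or self.n_female < 1:
            raise ValueError("need at least one sample per sex")
        if self.starter_mean <= 0:
            raise ValueError("starter_mean must be > 0")
        if not 0 <= self.spill_fraction < 1:
            raise ValueError("spill_fraction must lie in [0, 1)")
        for rid, base, mult in self.regions:
            if base < 0:
                raise ValueError(f"base_pps for region {rid} must be >= 0")
            if mult <= 0:
                raise ValueError(f"male_multiplier for region {rid} must be > 0")

    def expected_pps(self, sex: str) -> dict[int, float]:
        if sex == "male":
            return {rid: base * mult for rid, base, mult in self.regions}
        return {rid: base for rid, base, mult in self.regions}


# -- synthetic atlas -------------------------------------------------------


def make_synthetic_atlas(
    n_slices: int,
    n_regions: int,
    image_size: tuple[int, int] = (128, 128),
    seed: int = 0,
    pixel_size_um: float = 10.0,
) -> RegionAtlas:
    """Mosaic atlas: each slice is a Voronoi partition of an elliptical brain
    outline, mirrored about the vertical midline. Region ids 1..n_regions all
    appear in every slice; a root node (id n_regions + 1) parents every leaf.
    """
    h, w = image_size
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if h < 32 or w < 32:
        raise ValueError("image_size must be at least 32x32")
    rng = np.random.default_rng(seed)
    midline_x = w // 2

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    brain = ((yy - cy) / (0.45 * h)) ** 2 + ((xx - cx) / (0.45 * w)) ** 2 <= 1.0

    left = brain.copy()
    left[:, midline_x:] = False
    left_rows, left_cols = np.nonzero(left)
    if n_regions > left_rows.size:
        raise ValueError(
            f"n_regions={n_regions} exceeds representable patches "
            f"({left_rows.size} in-brain half-pixels)"
        )

    slices = []
    ap_values = np.round(np.linspace(3.0, -4.0, n_slices), 3)
    for si in range(n_slices):
        pick = rng.choice(left_rows.size, size=n_regions, replace=False)
        seeds = np.column_stack([left_rows[pick], left_cols[pick]]).astype(float)
        # nearest-seed labeling of the left half
        pts = np.column_stack([left_rows, left_cols]).astype(float)
        d2 = (
            (pts[:, None, 0] - seeds[None, :, 0]) ** 2
            + (pts[:, None, 1] - seeds[None, :, 1]) ** 2
        )
        nearest = np.argmin(d2, axis=1)
        # relabel patches by descending size so region 1 is always the
        # largest (a convenient injection target for downstream fixtures)
        sizes = np.bincount(nearest, minlength=n_regions)
        order = np.argsort(-sizes, kind="stable")
        relabel = np.empty(n_regions, dtype=np.int64)
        relabel[order] = np.arange(1, n_regions + 1)
        nearest = relabel[nearest]
        mask = np.zeros((h, w), dtype=np.int64)
        mask[left_rows, left_cols] = nearest
        # mirror left half onto the right: column c -> column w-1-c
        if w % 2 == 0:
            mask[:, midline_x:] = mask[:, :midline_x][:, ::-1]
        else:
            mask[:, midline_x + 1 :] = mask[:, :midline_x][:, ::-1]
            mask[:, midline_x] = mask[:, midline_x - 1]  # center column
        mask[~brain] = 0
        slices.append(
            AtlasSlice(
                label_mask=mask,
                ap_mm=float(ap_values[si]),
                pixel_size_um=pixel_size_um,
                midline_x=midline_x,
            )
        )

    root_id = n_regions + 1
    nodes = {
        root_id: RegionNode(root_id, "ROOT", "synthetic root", None, "meta")
    }
    for rid in range(1, n_regions + 1):
        nodes[rid] = RegionNode(rid, f"R{rid}", f"region {rid}", root_id, "leaf")
    return RegionAtlas(nodes=nodes, slices=slices)


# -- section rendering -----------------------------------------------------


def render_section(
    cells: Sequence[TruthCell],
    image_size: tuple[int, int],
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
) -> np.ndarray:
    """Render cells as Gaussian-blurred disks into a (2, h, w) image.

    Channel 0 is helper, channel 1 is rabies; "both" cells appear in each.
    Additive Gaussian background noise on top; deterministic for fixed seed.
    """
    h, w = image_size
    bad = [
        i
        for i, c in enumerate(cells)
        if not (0 <= c.x < w and 0 <= c.y < h)
    ]
    if bad:
        raise ValueError(f"cells out of image bounds at indices {bad}")
    canvas = np.zeros((2, h, w), dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for c in cells:
        # disk drawn on a local window for speed
        r = int(np.ceil(c.radius_px)) + 1
        y0, y1 = max(0, int(c.y) - r), min(h, int(c.y) + r + 1)
        x0, x1 = max(0, int(c.x) - r), min(w, int(c.x) + r + 1)
        win_y, win_x = yy[y0:y1, x0:x1], xx[y0:y1, x0:x1]
        disk = ((win_y - c.y) ** 2 + (win_x - c.x) ** 2) <= c.radius_px**2
        targets = (0, 1) if c.channel == "both" else ((0,) if c.channel == "helper" else (1,))
        for t in targets:
            np.maximum(
                canvas[t, y0:y1, x0:x1],
                disk * c.peak_intensity,
                out=canvas[t, y0:y1, x0:x1],
            )
    if noise.psf_sigma_px > 0:
        for t in range(2):
            canvas[t] = gaussian_filter(canvas[t], noise.psf_sigma_px)
    rng = np.random.default_rng(seed)
    background = rng.normal(
        noise.background_mean, noise.background_sd, size=canvas.shape
    )
    return np.clip(canvas + background, 0.0, None)


def place_cells_in_regions(
    atlas_slice: AtlasSlice,
    counts: dict[int, dict[str, int]],
    radius_px: float = 4.0,
    peak_intensity: float = 150.0,
    min_spacing_px: float | None = None,
    seed: int = 0,
) -> list[TruthCell]:
    """Place cells uniformly at random inside their regions' mask pixels.

    *counts* maps region_id -> {channel: n}. Cells keep *min_spacing_px*
    (default 4 * radius) between centroids so renders stay resolvable; raises
    if a region cannot host its requested cells at that spacing.
    """
    if min_spacing_px is None:
        min_spacing_px = 4.0 * radius_px
    rng = np.random.default_rng(seed)
    mask = atlas_slice.label_mask
    placed: list[TruthCell] = []
    occupied: list[tuple[float, float]] = []
    for rid in sorted(counts):
        rows, cols = np.nonzero(mask == rid)
        if rows.size == 0:
            raise ValueError(f"region {rid} absent from slice mask")
        for channel in ("helper", "rabies", "both"):
            n = counts[rid].get(channel, 0)
            for _ in range(n):
                for _attempt in range(2000):
                    i = rng.integers(rows.size)
                    x, y = float(cols[i]), float(rows[i])
                    if all(
                        (x - ox) ** 2 + (y - oy) ** 2 >= min_spacing_px**2
                        for ox, oy in occupied
                    ):
                        break
                else:
                    raise ValueError(
                        f"could not place {n} cells in region {rid} at spacing "
                        f"{min_spacing_px}"
                    )
                occupied.append((x, y))
                placed.append(
                    TruthCell(
                        x=x,
                        y=y,
                        radius_px=radius_px,
                        peak_intensity=peak_intensity,
                        channel=channel,
                        region_id=rid,
                        is_starter=channel == "both",
                    )
                )
    return placed


def match_to_truth(
    detected_xy: Sequence[tuple[float, float]],
    truth_xy: Sequence[tuple[float, float]],
    tol_px: float = 2.0,
) -> int:
    """One-to-one greedy match of detections to truth centroids within
    *tol_px*; returns the number of matched pairs (for recall/precision)."""
    cands = []
    for di, (dx, dy) in enumerate(detected_xy):
        for ti, (tx, ty) in enumerate(truth_xy):
            d = ((dx - tx) ** 2 + (dy - ty) ** 2) ** 0.5
            if d <= tol_px:
                cands.append((d, di, ti))
    cands.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    for _, di, ti in cands:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
    return len(used_d)


# -- cohort simulation -----------------------------------------------------


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float | None) -> int:
    if mean <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(mean))
    # negative binomial parameterized by mean and size (overdispersion switch)
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_cohort(
    spec: CohortSpec,
    atlas: RegionAtlas,
) -> tuple[list[HemisphereSample], dict[str, dict[int, float]]]:
    """Draw a full cohort of hemisphere samples from the generative model.

    Per hemisphere: total starters ~ Poisson(starter_mean) conditioned >= 1,
    split (1 - spill) into the target region and the spill fraction across the
    other spec regions; each region's presynaptic count ~ Poisson(pps * S)
    where pps carries the sex multiplier. Returns (samples, expected PPS per
    sex) — the truth table for calibration tests.
    """
    known = set(atlas.nodes)
    for rid, _, _ in spec.regions:
        if rid not in known:
            raise ValueError(f"spec region {rid} not in atlas")
    if spec.starter_target_region not in known:
        raise ValueError(f"starter target region {spec.starter_target_region} not in atlas")

    rng = np.random.default_rng(spec.seed)
    other_regions = [
        rid for rid, _, _ in spec.regions if rid != spec.starter_target_region
    ]
    samples: list[HemisphereSample] = []
    roster = [("male", i) for i in range(spec.n_male)] + [
        ("female", i) for i in range(spec.n_female)
    ]
    for sex, i in roster:
        total_starters = 0
        while total_starters < 1:
            total_starters = int(rng.poisson(spec.starter_mean))
        starters = {}
        n_spill = int(rng.binomial(total_starters, spec.spill_fraction))
        starters[spec.starter_target_region] = total_starters - n_spill
        if n_spill and other_regions:
            split = rng.multinomial(n_spill, np.full(len(other_regions), 1.0 / len(other_regions)))
            for rid, c in zip(other_regions, split):
                if c:
                    starters[rid] = starters.get(rid, 0) + int(c)
        elif n_spill:
            starters[spec.starter_target_region] += n_spill

        expected = spec.expected_pps(sex)
        presynaptic = {
            rid: _draw_count(rng, expected[rid] * total_starters, spec.dispersion)
            for rid, _, _ in spec.regions
        }
        samples.append(
            HemisphereSample(
                sample_id=f"{sex[0].upper()}{i + 1}",
                sex=sex,
                target="amygdala",
                side="left" if i % 2 == 0 else "right",
                starters=starters,
                presynaptic=presynaptic,
            )
        )
    truth = {
        "male": spec.expected_pps("male"),
        "female": spec.expected_pps("female"),
    }
    return samples, truth
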