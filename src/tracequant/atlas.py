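"""Region hierarchy, per-slice label masks, and the anterior-posterior analysis window.

The atlas is the coordinate frame all counts live in: a tree of brain regions
(each tagged with a reporting tier) plus a stack of 2-D integer label masks,
one per coronal slice, each annotated with its AP coordinate in mm from bregma.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile

__all__ = [
    "LEVEL_TAGS",
    "RegionNode",
    "AtlasSlice",
    "RegionAtlas",
    "AtlasError",
    "load_atlas",
    "save_atlas",
    "in_ap_window",
    "aggregate_counts",
]

LEVEL_TAGS = ("leaf", "summary", "meta")

#: Pseudo-region id for cells mapping outside the brain mask.
UNASSIGNED_ID = 0

DEFAULT_AP_WINDOW_MM = (3.5, -4.5)


class AtlasError(ValueError):
    """Structural or validation failure in atlas inputs."""


@dataclass(frozen=True)
class RegionNode:
    region_id: int
    acronym: str
    name: str
    parent_id: int | None
    level_tag: str = "leaf"

    def __post_init__(self) -> None:
        if self.region_id <= 0:
            raise AtlasError(f"region_id must be positive, got {self.region_id}")
        if self.level_tag not in LEVEL_TAGS:
            raise AtlasError(
                f"level_tag must be one of {LEVEL_TAGS}, got {self.level_tag!r}"
            )


@dataclass(frozen=True)
class AtlasSlice:
    label_mask: np.ndarray
    ap_mm: float
    pixel_size_um: float
    midline_x: int

    def __post_init__(self) -> None:
        mask = np.asarray(self.label_mask)
        if mask.ndim != 2:
            raise AtlasError("label_mask must be a 2-D integer image")
        if not np.issubdtype(mask.dtype, np.integer):
            raise AtlasError(f"label_mask must be integer-typed, got {mask.dtype}")
        if self.pixel_size_um <= 0:
            raise AtlasError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not 0 <= self.midline_x < mask.shape[1]:
            raise AtlasError("midline_x outside mask columns")
        object.__setattr__(self, "label_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_mask.shape


@dataclass
class RegionAtlas:
    nodes: dict[int, RegionNode]
    slices: list[AtlasSlice]
    ap_window_mm: tuple[float, float] = DEFAULT_AP_WINDOW_MM

    def __post_init__(self) -> None:
        self._validate_hierarchy()
        self._validate_slices()
        ap_max, ap_min = self.ap_window_mm
        if not ap_max > ap_min:
            raise AtlasError(
                f"ap_window_mm must be (max, min) with max > min, got {self.ap_window_mm}"
            )

    # -- hierarchy ---------------------------------------------------------

    def _validate_hierarchy(self) -> None:
        nodes = self.nodes
        roots = [n for n in nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise AtlasError(f"hierarchy must have exactly one root, found {len(roots)}")
        for node in nodes.values():
            if node.parent_id is not None and node.parent_id not in nodes:
                raise AtlasError(
                    f"node {node.region_id} ({node.acronym}) has unknown parent "
                    f"{node.parent_id}"
                )
        # cycle check by walking every parent chain
        for node in nodes.values():
            seen = {node.region_id}
            cur = node
            while cur.parent_id is not None:
                if cur.parent_id in seen:
                    raise AtlasError(
                        f"cyclic hierarchy involving region {cur.parent_id}"
                    )
                seen.add(cur.parent_id)
                cur = nodes[cur.parent_id]

    def _validate_slices(self) -> None:
        known = set(self.nodes)
        aps = [s.ap_mm for s in self.slices]
        if any(b >= a for a, b in zip(aps, aps[1:])):
            raise AtlasError("slice ap_mm values must be strictly decreasing")
        for i, sl in enumerate(self.slices):
            present = set(np.unique(sl.label_mask)) - {UNASSIGNED_ID}
            undeclared = present - known
            if undeclared:
                raise AtlasError(
                    f"slice {i} mask contains undeclared region ids: "
                    f"{sorted(int(u) for u in undeclared)}"
                )

    @property
    def root(self) -> RegionNode:
        return next(n for n in self.nodes.values() if n.parent_id is None)

    def ancestors(self, region_id: int) -> list[RegionNode]:
        """Path from *region_id* (inclusive) to the root."""
        if region_id not in self.nodes:
            raise AtlasError(f"unknown region_id {region_id}")
        path = [self.nodes[region_id]]
        while path[-1].parent_id is not None:
            path.append(self.nodes[path[-1].parent_id])
        return path

    def subtree_ids(self, region_id: int) -> set[int]:
        """All region ids at or below *region_id*."""
        if region_id not in self.nodes:
            raise AtlasError(f"unknown region_id {region_id}")
        children: dict[int, list[int]] = {}
        for n in self.nodes.values():
            if n.parent_id is not None:
                children.setdefault(n.parent_id, []).append(n.region_id)
        out: set[int] = set()
        stack = [region_id]
        while stack:
            rid = stack.pop()
            out.add(rid)
            stack.extend(children.get(rid, ()))
        return out

    def leaf_ids(self) -> list[int]:
        return sorted(
            n.region_id for n in self.nodes.values() if n.level_tag == "leaf"
        )


def in_ap_window(atlas: RegionAtlas, ap_mm: float) -> bool:
    """True iff *ap_mm* lies within the closed analysis window.

    Boundaries are inclusive; slices anterior/posterior of the window (e.g.
    olfactory bulb, cerebellum planes) are excluded from all quantification.
    """
    ap_max, ap_min = atlas.ap_window_mm
    return ap_min <= ap_mm <= ap_max


def aggregate_counts(
    counts: Mapping[int, int | float],
    atlas: RegionAtlas,
    level_tag: str,
) -> dict[int, int | float]:
    """Roll counts up to the nearest ancestor-or-self carrying *level_tag*.

    Counts with no tagged ancestor accumulate under the root. Totals are
    conserved exactly.
    """
    if level_tag not in LEVEL_TAGS:
        raise AtlasError(f"level_tag must be one of {LEVEL_TAGS}, got {level_tag!r}")
    out: dict[int, int | float] = {}
    root_id = atlas.root.region_id
    for rid, count in counts.items():
        target = root_id
        for node in atlas.ancestors(rid):  # raises AtlasError on unknown id
            if node.level_tag == level_tag:
                target = node.region_id
                break
        out[target] = out.get(target, 0) + count
    return out


# -- persistence -----------------------------------------------------------
#
# hierarchy: JSON list of {id, acronym, name, parent_id, level_tag}
# masks: multi-page 16-bit TIFF, page order == sidecar order
# sidecar: JSON {ap_window_mm, slices: [{ap_mm, pixel_size_um, midline_x}]}


def load_atlas(
    hierarchy_file: str | Path,
    mask_stack_file: str | Path,
    meta_file: str | Path,
) -> RegionAtlas:
    with open(hierarchy_file) as fh:
        records = json.load(fh)
    nodes = {
        int(r["id"]): RegionNode(
            region_id=int(r["id"]),
            acronym=r["acronym"],
            name=r.get("name", r["acronym"]),
            parent_id=None if r["parent_id"] is None else int(r["parent_id"]),
            level_tag=r.get("level_tag", "leaf"),
        )
        for r in records
    }
    if len(nodes) != len(records):
        raise AtlasError("duplicate region ids in hierarchy file")

    pages = tifffile.imread(mask_stack_file)
    if pages.ndim == 2:
        pages = pages[None]
    with open(meta_file) as fh:
        meta = json.load(fh)
    if len(meta["slices"]) != len(pages):
        raise AtlasError(
            f"mask stack has {len(pages)} pages but sidecar lists "
            f"{len(meta['slices'])} slices"
        )
    slices = [
        AtlasSlice(
            label_mask=page.astype(np.int64),
            ap_mm=float(m["ap_mm"]),
            pixel_size_um=float(m["pixel_size_um"]),
            midline_x=int(m["midline_x"]),
        )
        for page, m in zip(pages, meta["slices"])
    ]
    window = tuple(meta.get("ap_window_mm", DEFAULT_AP_WINDOW_MM))
    return RegionAtlas(nodes=nodes, slices=slices, ap_window_mm=window)


def save_atlas(
    atlas: RegionAtlas,
    hierarchy_file: str | Path,
    mask_stack_file: str | Path,
    meta_file: str | Path,
) -> None:
    records = [
        {
            "id": n.region_id,
            "acronym": n.acronym,
            "name": n.name,
            "parent_id": n.parent_id,
            "level_tag": n.level_tag,
        }
        for n in sorted(atlas.nodes.values(), key=lambda n: n.region_id)
    ]
    with open(hierarchy_file, "w") as fh:
        json.dump(records, fh, indent=1)
    stack = np.stack([s.label_mask.astype(np.uint16) for s in atlas.slices])
    tifffile.imwrite(mask_stack_file, stack)
    meta = {
        "ap_window_mm": list(atlas.ap_window_mm),
        "slices": [
            {
                "ap_mm": s.ap_mm,
                "pixel_size_um": s.pixel_size_um,
                "midline_x": s.midline_x,
            }
            for s in atlas.slices
        ],
    }
    with open(meta_file, "w") as fh:
        json.dump(meta, fh, indent=1)
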