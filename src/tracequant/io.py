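"""Plain-text serialization: truth tables, detections, cell calls, landmarks,
cohort count tables, and statistics results. All tables are CSV via pandas;
structured metadata is JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .detection import CellCall, Detection
from .fixtures import TruthCell
from .quantify import HemisphereSample
from .registration import LandmarkSet
from .stats import CohortResult

__all__ = [
    "write_truth_cells",
    "read_truth_cells",
    "write_detections",
    "read_detections",
    "write_calls",
    "read_calls",
    "write_landmarks",
    "read_landmarks",
    "write_cohort",
    "read_cohort",
    "write_results",
    "write_exclusion_log",
]


def write_truth_cells(cells: Sequence[TruthCell], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "x": c.x,
                "y": c.y,
                "radius_px": c.radius_px,
                "peak_intensity": c.peak_intensity,
                "channel": c.channel,
                "region_id": c.region_id,
                "is_starter": c.is_starter,
            }
            for c in cells
        ],
        columns=["x", "y", "radius_px", "peak_intensity", "channel", "region_id", "is_starter"],
    ).to_csv(path, index=False)


def read_truth_cells(path: str | Path) -> list[TruthCell]:
    df = pd.read_csv(path)
    return [
        TruthCell(
            x=float(r.x),
            y=float(r.y),
            radius_px=float(r.radius_px),
            peak_intensity=float(r.peak_intensity),
            channel=str(r.channel),
            region_id=int(r.region_id),
            is_starter=bool(r.is_starter),
        )
        for r in df.itertuples()
    ]


def write_detections(detections: Sequence[Detection], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "x": d.centroid[0],
                "y": d.centroid[1],
                "area_px": d.area_px,
                "circularity": d.circularity,
                "snr": d.snr,
                "mean_intensity": d.mean_intensity,
                "channel": d.channel,
            }
            for d in detections
        ],
        columns=["x", "y", "area_px", "circularity", "snr", "mean_intensity", "channel"],
    ).to_csv(path, index=False)


def read_detections(path: str | Path) -> list[Detection]:
    df = pd.read_csv(path)
    return [
        Detection(
            centroid=(float(r.x), float(r.y)),
            area_px=int(r.area_px),
            circularity=float(r.circularity),
            snr=float(r.snr),
            mean_intensity=float(r.mean_intensity),
            channel=str(r.channel),
        )
        for r in df.itertuples()
    ]


def write_calls(calls: Sequence[CellCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "x": c.centroid[0],
                "y": c.centroid[1],
                "kind": c.kind,
                "region_id": "" if c.region_id is None else c.region_id,
                "hemisphere": c.hemisphere or "",
            }
            for c in calls
        ],
        columns=["x", "y", "kind", "region_id", "hemisphere"],
    ).to_csv(path, index=False)


def read_calls(path: str | Path) -> list[CellCall]:
    df = pd.read_csv(path, keep_default_na=False)
    calls = []
    for r in df.itertuples():
        rid = r.region_id
        calls.append(
            CellCall(
                centroid=(float(r.x), float(r.y)),
                kind=str(r.kind),
                region_id=None if rid == "" else int(float(rid)),
                hemisphere=str(r.hemisphere) or None,
            )
        )
    return calls


def write_landmarks(landmark_sets: Sequence[LandmarkSet], path: str | Path) -> None:
    rows = []
    for ls in landmark_sets:
        for (ix, iy), (ax, ay) in ls.pairs:
            rows.append(
                {
                    "section_id": ls.section_id,
                    "ap_mm": ls.ap_mm,
                    "img_x": ix,
                    "img_y": iy,
                    "atlas_x": ax,
                    "atlas_y": ay,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(path: str | Path) -> list[LandmarkSet]:
    df = pd.read_csv(path)
    out = []
    for section_id, grp in df.groupby("section_id", sort=True):
        out.append(
            LandmarkSet.from_arrays(
                grp[["img_x", "img_y"]].to_numpy(),
                grp[["atlas_x", "atlas_y"]].to_numpy(),
                section_id=str(section_id),
                ap_mm=float(grp["ap_mm"].iloc[0]),
            )
        )
    return out


def write_cohort(samples: Sequence[HemisphereSample], path: str | Path) -> None:
    """Long-format counts: one row per (sample, region)."""
    rows = []
    for s in samples:
        regions = sorted(set(s.starters) | set(s.presynaptic))
        for rid in regions:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "sex": s.sex,
                    "target": s.target,
                    "side": s.side,
                    "region_id": rid,
                    "starters": s.starters.get(rid, 0),
                    "presynaptic": s.presynaptic.get(rid, 0),
                }
            )
    columns = ["sample_id", "sex", "target", "side", "region_id", "starters", "presynaptic"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[HemisphereSample]:
    df = pd.read_csv(path)
    if df.empty:
        return []
    samples = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        first = grp.iloc[0]
        samples.append(
            HemisphereSample(
                sample_id=str(sample_id),
                sex=str(first.sex),
                target=str(first.target),
                side=str(first.side),
                starters={
                    int(r.region_id): int(r.starters)
                    for r in grp.itertuples()
                    if r.starters > 0
                },
                presynaptic={
                    int(r.region_id): int(r.presynaptic)
                    for r in grp.itertuples()
                    if r.presynaptic > 0
                },
            )
        )
    return samples


def write_results(
    result: CohortResult, path: str | Path, acronyms: dict[int, str] | None = None
) -> None:
    acronyms = acronyms or {}
    pd.DataFrame(
        [
            {
                "region_id": c.region_id,
                "acronym": acronyms.get(c.region_id, str(c.region_id)),
                "metric": c.metric,
                "n_male": result.n_male,
                "n_female": result.n_female,
                "male_mean": c.male_mean,
                "female_mean": c.female_mean,
                "direction": c.direction,
                "p": c.p_value,
                "q": c.q_value,
                "significant": c.significant,
            }
            for c in result.comparisons
        ]
    ).to_csv(path, index=False)


def write_exclusion_log(log: Sequence[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
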