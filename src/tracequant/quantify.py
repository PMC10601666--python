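"""Per-hemisphere count tables, QC gates, and connectivity metrics.

The experimental unit is one injected hemisphere. Counts from its sections
(restricted to the AP analysis window) are pooled, quality-controlled on
starter number and starter concentration in the injection target, and turned
into three normalized metrics:

* PPS  — presynaptic cells in a region / total starters in the sample
* FPR  — presynaptic cells in a region / total presynaptic in the sample
* starter distribution — starters in a region / total starters
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .atlas import UNASSIGNED_ID, RegionAtlas, in_ap_window
from .detection import CellCall

__all__ = [
    "HemisphereSample",
    "QuantMetrics",
    "SectionCalls",
    "QCParams",
    "qc_pass",
    "compute_metrics",
    "region_inclusion",
    "build_cohort",
]

SEXES = ("male", "female")


@dataclass
class HemisphereSample:
    sample_id: str
    sex: str
    target: str  # injection target, e.g. "amygdala" or "ORB"
    side: str  # "left" | "right"
    starters: dict[int, int] = field(default_factory=dict)
    presynaptic: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        for name, counts in (("starters", self.starters), ("presynaptic", self.presynaptic)):
            for rid, c in counts.items():
                if int(c) != c or c < 0:
                    raise ValueError(
                        f"{name}[{rid}] must be a nonnegative integer, got {c}"
                    )

    @property
    def total_starters(self) -> int:
        return sum(self.starters.values())

    @property
    def total_presynaptic(self) -> int:
        return sum(self.presynaptic.values())


@dataclass(frozen=True)
class QuantMetrics:
    pps: dict[int, float]
    fpr: dict[int, float]
    starter_dist: dict[int, float]
    total_starters: int
    total_presynaptic: int


@dataclass(frozen=True)
class QCParams:
    min_starters: int = 20
    min_target_fraction: float = 0.6


def qc_pass(
    sample: HemisphereSample,
    target_regions: set[int],
    min_starters: int = 20,
    min_target_fraction: float = 0.6,
) -> tuple[bool, str]:
    """Starter-count and injection-accuracy gates.

    Passes iff total starters >= *min_starters* (inclusive) AND the fraction
    of starters inside *target_regions* (the injection target's subtree)
    strictly exceeds *min_target_fraction*. Returns (ok, reason); reason names
    the first failed gate, or "ok".
    """
    total = sample.total_starters
    if total < min_starters:
        return False, (
            f"minimum of {min_starters} starter cells not met ({total} detected)"
        )
    in_target = sum(c for rid, c in sample.starters.items() if rid in target_regions)
    frac = in_target / total
    if not frac > min_target_fraction:
        return False, (
            f"over {min_target_fraction:.0%} of starters must lie in the target "
            f"({frac:.1%} observed)"
        )
    return True, "ok"


def compute_metrics(sample: HemisphereSample) -> QuantMetrics:
    """Compute PPS, FPR, and starter distribution for one hemisphere.

    Unassigned cells (region 0) participate in the denominators and appear as
    an explicit pseudo-region so that FPR and starter_dist each sum to 1.
    """
    total_s = sample.total_starters
    total_p = sample.total_presynaptic
    if total_s == 0:
        raise ValueError(
            f"sample {sample.sample_id}: PPS undefined with zero starters"
        )
    if total_p == 0:
        raise ValueError(
            f"sample {sample.sample_id}: FPR undefined with zero presynaptic cells"
        )
    pps = {rid: c / total_s for rid, c in sample.presynaptic.items()}
    fpr = {rid: c / total_p for rid, c in sample.presynaptic.items()}
    starter_dist = {rid: c / total_s for rid, c in sample.starters.items()}
    return QuantMetrics(
        pps=pps,
        fpr=fpr,
        starter_dist=starter_dist,
        total_starters=total_s,
        total_presynaptic=total_p,
    )


def region_inclusion(
    samples: Sequence[HemisphereSample],
    min_mean: float = 30.0,
) -> set[int]:
    """Regions whose mean presynaptic count strictly exceeds *min_mean* in
    either sex. The unassigned pseudo-region never qualifies."""
    by_sex: dict[str, list[HemisphereSample]] = {s: [] for s in SEXES}
    for sample in samples:
        by_sex[sample.sex].append(sample)
    for sex, group in by_sex.items():
        if not group:
            raise ValueError(f"region_inclusion requires >= 1 {sex} sample")
    regions = set()
    for sample in samples:
        regions.update(sample.presynaptic)
    regions.discard(UNASSIGNED_ID)
    included = set()
    for rid in regions:
        for group in by_sex.values():
            mean = sum(s.presynaptic.get(rid, 0) for s in group) / len(group)
            if mean > min_mean:
                included.add(rid)
                break
    return included


@dataclass(frozen=True)
class SectionCalls:
    """Region-assigned cell calls from one section of one hemisphere."""

    sample_id: str
    sex: str
    target: str
    side: str
    ap_mm: float
    calls: tuple[CellCall, ...]

    def __post_init__(self) -> None:
        for c in self.calls:
            if c.region_id is None:
                raise ValueError(
                    f"section of {self.sample_id}: calls must be region-assigned"
                )


def build_cohort(
    sections: Iterable[SectionCalls],
    atlas: RegionAtlas,
    target_regions_by_target: Mapping[str, set[int]],
    qc: QCParams = QCParams(),
) -> tuple[list[HemisphereSample], list[dict]]:
    """Pool sections into hemisphere samples, apply QC, log exclusions.

    Sections outside the atlas AP window are dropped before counting. Returns
    (QC-passing samples sorted by id, exclusion log); each log entry carries
    sample_id and the failed gate's reason.
    """
    pooled: dict[str, HemisphereSample] = {}
    for sec in sections:
        if sec.sample_id in pooled:
            ref = pooled[sec.sample_id]
            if (ref.sex, ref.target, ref.side) != (sec.sex, sec.target, sec.side):
                raise ValueError(
                    f"duplicate sample_id {sec.sample_id!r} with conflicting metadata"
                )
        else:
            pooled[sec.sample_id] = HemisphereSample(
                sample_id=sec.sample_id,
                sex=sec.sex,
                target=sec.target,
                side=sec.side,
            )
        if not in_ap_window(atlas, sec.ap_mm):
            continue
        sample = pooled[sec.sample_id]
        for call in sec.calls:
            rid = int(call.region_id)
            if call.kind == "starter":
                sample.starters[rid] = sample.starters.get(rid, 0) + 1
            elif call.kind == "presynaptic":
                sample.presynaptic[rid] = sample.presynaptic.get(rid, 0) + 1
            # helper_only cells carry no count

    passing: list[HemisphereSample] = []
    log: list[dict] = []
    for sample_id in sorted(pooled):
        sample = pooled[sample_id]
        try:
            target_regions = target_regions_by_target[sample.target]
        except KeyError:
            raise ValueError(
                f"no target region set declared for target {sample.target!r}"
            ) from None
        ok, reason = qc_pass(
            sample,
            target_regions,
            min_starters=qc.min_starters,
            min_target_fraction=qc.min_target_fraction,
        )
        if ok:
            passing.append(sample)
        else:
            log.append(
                {
                    "sample_id": sample.sample_id,
                    "sex": sample.sex,
                    "target": sample.target,
                    "side": sample.side,
                    "total_starters": sample.total_starters,
                    "reason": reason,
                }
            )
    return passing, log
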