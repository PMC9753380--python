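"""Candidate locus discovery from placed informative reads.

Anchored and clip records are binned by repeat unit, then scanned in
genomic order for clusters. A cluster grows and shrinks around the
running median of its members' positions — reads further than the 98th
fragment-length percentile + 100 bp from the centre are dropped, reads
within range admitted — until the membership stabilises or a left-clip
boundary is found. Accepted clusters need at least ``min_support``
informative reads from a single sample, at least one of them anchored.
Soft-clip edges, when present, give base-pair bounds; otherwise the
locus is the median anchored position.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .config import SweepConfig, DEFAULT_CONFIG
from .extract import EvidenceClass, FragmentStats, InformativeRead

_PLACED = {EvidenceClass.ANCHORED, EvidenceClass.CLIP_LEFT, EvidenceClass.CLIP_RIGHT}
_MAX_CLUSTER_ITERATIONS = 100


@dataclass
class LocusBounds:
    """A candidate expansion interval (0-based, half-open) with one repeat unit."""

    chrom: str
    left: int
    right: int
    unit: str
    left_from_clip: bool = False
    right_from_clip: bool = False
    n_support_per_sample: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.left > self.right:
            raise ValueError("LocusBounds requires left <= right")

    @property
    def max_support(self) -> int:
        return max(self.n_support_per_sample.values(), default=0)


@dataclass
class ReadCluster:
    chrom: str
    unit: str
    members: list[InformativeRead]

    def max_per_sample_support(self) -> int:
        return max(Counter(r.sample for r in self.members).values(), default=0)

    def n_anchored(self) -> int:
        return sum(1 for r in self.members
                   if r.evidence_class is EvidenceClass.ANCHORED)


def _accepted(cluster: ReadCluster, cfg: SweepConfig) -> bool:
    return (cluster.max_per_sample_support() >= cfg.min_support
            and cluster.n_anchored() >= 1)


def cluster_informative_reads(
    records: Iterable[InformativeRead],
    slack: float,
    cfg: SweepConfig = DEFAULT_CONFIG,
) -> list[ReadCluster]:
    """Greedy per-unit clustering of placed records.

    ``slack`` is the clustering half-window, normally
    ``cfg.cluster_slack(frag.p98)``. Records are sorted internally, so
    shuffled input yields identical clusters. Returns accepted clusters
    only; rejected seeds are consumed one record at a time so later
    records can still seed.
    """
    placed = [r for r in records if r.evidence_class in _PLACED]
    placed.sort(key=lambda r: (r.unit, r.chrom, r.position,
                               r.evidence_class.value, r.sample))
    clusters: list[ReadCluster] = []

    groups: dict[tuple[str, str], list[InformativeRead]] = {}
    for r in placed:
        groups.setdefault((r.unit, r.chrom), []).append(r)

    for (unit, chrom), group in groups.items():
        claimed = [False] * len(group)
        for seed_idx in range(len(group)):
            if claimed[seed_idx]:
                continue
            members = {seed_idx}
            for _ in range(_MAX_CLUSTER_ITERATIONS):
                center = statistics.median([group[i].position for i in members])
                window = {
                    i for i in range(len(group))
                    if not claimed[i] and abs(group[i].position - center) <= slack
                }
                window.add(seed_idx)
                stable = window == members
                members = window
                if stable:
                    break
                # a left clip pins the locus: recentre on it, admit once, stop
                left_clips = [group[i].position for i in members
                              if group[i].evidence_class is EvidenceClass.CLIP_LEFT]
                if left_clips:
                    center = _modal_coordinate(left_clips)
                    members = {
                        i for i in range(len(group))
                        if not claimed[i] and abs(group[i].position - center) <= slack
                    }
                    members.add(seed_idx)
                    break
            cluster = ReadCluster(chrom, unit, [group[i] for i in sorted(members)])
            if _accepted(cluster, cfg):
                for i in members:
                    claimed[i] = True
                clusters.append(cluster)
            else:
                claimed[seed_idx] = True
    return clusters


def _modal_coordinate(values: Sequence[int]) -> int:
    """Most frequent coordinate; ties broken toward the smaller one."""
    counts = Counter(values)
    return min(counts, key=lambda v: (-counts[v], v))


def infer_bounds(cluster: ReadCluster) -> LocusBounds:
    """Derive base-pair bounds for an accepted cluster.

    Soft-clip edges define bounds where observed (modal coordinate);
    otherwise the locus collapses to the median anchored position.
    """
    left_clips = [r.split_position for r in cluster.members
                  if r.evidence_class is EvidenceClass.CLIP_LEFT]
    right_clips = [r.split_position for r in cluster.members
                   if r.evidence_class is EvidenceClass.CLIP_RIGHT]
    anchored = [r.position for r in cluster.members
                if r.evidence_class is EvidenceClass.ANCHORED]

    if left_clips:
        left = _modal_coordinate(left_clips)
        left_from_clip = True
    else:
        left = int(statistics.median_low(anchored))
        left_from_clip = False
    if right_clips:
        right = max(left, _modal_coordinate(right_clips))
        right_from_clip = True
    else:
        right = left
        right_from_clip = False

    support = Counter(r.sample for r in cluster.members)
    return LocusBounds(
        chrom=cluster.chrom, left=left, right=right, unit=cluster.unit,
        left_from_clip=left_from_clip, right_from_clip=right_from_clip,
        n_support_per_sample=dict(support),
    )


def discover_loci(
    records: Iterable[InformativeRead],
    frag: FragmentStats,
    cfg: SweepConfig = DEFAULT_CONFIG,
) -> list[LocusBounds]:
    """Single-sample locus discovery: cluster then infer bounds."""
    slack = cfg.cluster_slack(frag.p98)
    loci = [infer_bounds(c) for c in cluster_informative_reads(records, slack, cfg)]
    loci.sort(key=lambda b: (b.chrom, b.left, b.unit))
    return _merge_same_unit_overlaps(loci)


def joint_merge(
    per_sample_records: dict[str, Iterable[InformativeRead]],
    frag_per_sample: dict[str, FragmentStats],
    cfg: SweepConfig = DEFAULT_CONFIG,
) -> list[LocusBounds]:
    """Pool evidence across samples and discover shared locus bounds.

    The clustering window uses the largest per-sample 98th percentile, so
    the loosest library dominates. A locus is kept only when at least one
    sample alone contributes ``min_support`` reads.
    """
    if not per_sample_records:
        raise ValueError("joint_merge requires at least one sample")
    pooled = [r for recs in per_sample_records.values() for r in recs]
    max_p98 = max(frag_per_sample[s].p98 for s in per_sample_records)
    slack = cfg.cluster_slack(max_p98)
    loci = [infer_bounds(c) for c in cluster_informative_reads(pooled, slack, cfg)]
    loci.sort(key=lambda b: (b.chrom, b.left, b.unit))
    return _merge_same_unit_overlaps(loci)


def _merge_same_unit_overlaps(loci: list[LocusBounds]) -> list[LocusBounds]:
    """Enforce: loci with identical (chrom, unit) never overlap."""
    out: list[LocusBounds] = []
    for locus in loci:
        prev = next((p for p in reversed(out)
                     if p.chrom == locus.chrom and p.unit == locus.unit), None)
        if prev is not None and locus.left < max(prev.right, prev.left + 1):
            prev.right = max(prev.right, locus.right)
            prev.left_from_clip = prev.left_from_clip or locus.left_from_clip
            prev.right_from_clip = prev.right_from_clip or locus.right_from_clip
            for s, n in locus.n_support_per_sample.items():
                prev.n_support_per_sample[s] = prev.n_support_per_sample.get(s, 0) + n
        else:
            out.append(locus)
    return out


_BOUNDS_HEADER = ["chrom", "left", "right", "unit", "left_clip", "right_clip",
                  "max_support"]


def write_bounds(loci: Iterable[LocusBounds], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_BOUNDS_HEADER) + "\n")
        for b in loci:
            fh.write("\t".join([
                b.chrom, str(b.left), str(b.right), b.unit,
                "1" if b.left_from_clip else "0",
                "1" if b.right_from_clip else "0",
                str(b.max_support),
            ]) + "\n")


def read_bounds(path: str | Path) -> list[LocusBounds]:
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _BOUNDS_HEADER:
            raise ValueError(f"{path}: bad bounds header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            loci.append(LocusBounds(
                chrom=f[0], left=int(f[1]), right=int(f[2]), unit=f[3],
                left_from_clip=f[4] == "1", right_from_clip=f[5] == "1",
                n_support_per_sample={"pooled": int(f[6])},
            ))
    return loci
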