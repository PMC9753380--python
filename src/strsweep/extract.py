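"""Informative-read extraction from alignment files.

Reads whose alignments differ from the reference (mismatches, indels,
clips), that fall in known repeat sinks, or that are unmapped/low-MAPQ
are scored for STR content. A repeat-laden read with a well-mapped,
non-repetitive mate is repositioned one median fragment length from the
mate (an *anchored pair*); when both mates are repeat-laden or the mate
is poorly mapped the pair is recorded once, without a position (an
*unplaced pair*). Informative soft-clipped segments produce clip records
whose coordinates mark candidate insertion breakpoints.
"""

from __future__ import annotations

import enum
import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .config import SweepConfig, DEFAULT_CONFIG
from .kmers import KmerProfile, representative_unit
from .sinks import SinkLookup, SinkRegion


class EvidenceClass(str, enum.Enum):
    ANCHORED = "ANCHORED"
    UNPLACED = "UNPLACED"
    CLIP_LEFT = "CLIP_LEFT"
    CLIP_RIGHT = "CLIP_RIGHT"
    SPANNING = "SPANNING"
    OVERLAPPING = "OVERLAPPING"
    SPANNING_PAIR = "SPANNING_PAIR"


@dataclass(frozen=True)
class FragmentStats:
    """Median and 98th percentile of the sample's fragment (insert) sizes."""

    median: int
    p98: int
    n_observations: int

    def __post_init__(self) -> None:
        if not (0 < self.median <= self.p98):
            raise ValueError("require 0 < median <= p98")


@dataclass
class InformativeRead:
    """One piece of repeat evidence, placed at its inferred genomic origin."""

    sample: str
    chrom: str | None
    position: int | None
    unit: str
    evidence_class: EvidenceClass
    repeat_count: int
    split_position: int | None = None

    def __post_init__(self) -> None:
        placed = {EvidenceClass.ANCHORED, EvidenceClass.CLIP_LEFT, EvidenceClass.CLIP_RIGHT}
        if self.evidence_class in placed and (self.chrom is None or self.position is None):
            raise ValueError(f"{self.evidence_class.value} record requires chrom+position")
        if self.evidence_class is EvidenceClass.UNPLACED and self.position is not None:
            raise ValueError("UNPLACED record carries no position")
        if self.repeat_count < 0:
            raise ValueError("repeat_count must be >= 0")


MAX_TEMPLATE_LEN = 2000
MIN_FRAGMENT_OBSERVATIONS = 1000


def estimate_fragment_stats(
    alignment: str | Path | pysam.AlignmentFile,
    max_sample: int = 100_000,
    cfg: SweepConfig = DEFAULT_CONFIG,
    min_observations: int = MIN_FRAGMENT_OBSERVATIONS,
) -> FragmentStats:
    """Empirical fragment-length median and 98th percentile for one sample.

    Uses the absolute template lengths of the first ``max_sample`` proper
    pairs with MAPQ >= ``cfg.min_mapq``, capped at 2,000 bp; fails when
    fewer than ``min_observations`` usable pairs exist.
    """
    own = not isinstance(alignment, pysam.AlignmentFile)
    bam = pysam.AlignmentFile(str(alignment)) if own else alignment
    try:
        lengths: list[int] = []
        for read in bam.fetch(until_eof=True):
            if (not read.is_proper_pair or read.is_secondary or read.is_supplementary
                    or read.is_duplicate or read.is_read2):
                continue
            if read.mapping_quality < cfg.min_mapq:
                continue
            tlen = abs(read.template_length)
            if 0 < tlen <= MAX_TEMPLATE_LEN:
                lengths.append(tlen)
            if len(lengths) >= max_sample:
                break
    finally:
        if own:
            bam.close()
    return fragment_stats_from_lengths(lengths, min_observations)


def fragment_stats_from_lengths(
    lengths: Iterable[int], min_observations: int = MIN_FRAGMENT_OBSERVATIONS
) -> FragmentStats:
    arr = np.asarray(list(lengths))
    if arr.size < min_observations:
        raise ValueError(
            f"only {arr.size} usable proper pairs (< {min_observations}); "
            "sample unusable for fragment-length estimation"
        )
    median = int(np.percentile(arr, 50, method="lower"))
    p98 = int(np.percentile(arr, 98, method="lower"))
    return FragmentStats(median=median, p98=p98, n_observations=int(arr.size))


def _is_primary(read: pysam.AlignedSegment) -> bool:
    return not (read.is_secondary or read.is_supplementary or read.is_duplicate)


def _is_imperfect(read: pysam.AlignedSegment) -> bool:
    """True when the alignment differs from the reference."""
    if read.cigartuples is None:
        return True
    for op, _ in read.cigartuples:
        if op in (1, 2, 4):  # I, D, S
            return True
    if read.has_tag("NM") and read.get_tag("NM") > 0:
        return True
    return False


def select_candidate_reads(
    alignment: pysam.AlignmentFile,
    sinks: SinkLookup,
    cfg: SweepConfig = DEFAULT_CONFIG,
) -> Iterator[pysam.AlignedSegment]:
    """Yield primary reads worth scoring for STR content.

    Candidates are unmapped reads, low-MAPQ reads, reads overlapping a
    sink region, and reads with a non-perfect alignment; perfectly
    aligned reads outside sinks are skipped.
    """
    for read in alignment.fetch(until_eof=True):
        if not _is_primary(read):
            continue
        if read.is_unmapped or read.mapping_quality < cfg.min_mapq:
            yield read
            continue
        if sinks.overlaps(read.reference_name, read.reference_start, read.reference_end):
            yield read
            continue
        if _is_imperfect(read):
            yield read


def _soft_clips(read: pysam.AlignedSegment) -> list[tuple[str, str, int]]:
    """(side, clipped sequence, clip coordinate) for terminal soft clips."""
    out = []
    ct = read.cigartuples
    if not ct or read.is_unmapped:
        return out
    seq = read.query_sequence or ""
    if ct[0][0] == 4:
        out.append(("left", seq[: ct[0][1]], read.reference_start))
    if ct[-1][0] == 4:
        out.append(("right", seq[len(seq) - ct[-1][1]:], read.reference_end))
    return out


def _anchor_position(mate: pysam.AlignedSegment, frag: FragmentStats,
                     contig_len: int) -> int:
    """Inferred STR-read origin: one median fragment length from the mate.

    A forward-strand mate anchors downstream of its 5' mapping position;
    a reverse-strand mate anchors upstream of the fragment's outer end.
    """
    if mate.is_reverse:
        pos = mate.reference_end - frag.median
    else:
        pos = mate.reference_start + frag.median
    return max(0, min(pos, contig_len - 1))


def classify_and_place(
    read_pair: tuple[pysam.AlignedSegment | None, pysam.AlignedSegment | None],
    profile_r1: KmerProfile | None,
    profile_r2: KmerProfile | None,
    frag: FragmentStats,
    cfg: SweepConfig = DEFAULT_CONFIG,
    sinks: SinkLookup | None = None,
    sample: str = "sample",
    contig_lengths: dict[str, int] | None = None,
) -> list[InformativeRead]:
    """Turn one template's mates + k-mer profiles into evidence records.

    Produces at most one ANCHORED or one UNPLACED record per template,
    plus any CLIP records from informative soft-clipped segments.
    """
    contig_lengths = contig_lengths or {}
    records: list[InformativeRead] = []
    reads = list(read_pair)
    profiles = [profile_r1, profile_r2]

    # clip records are independent of the pair classification
    for read in reads:
        if read is None or not _is_primary(read):
            continue
        for side, clip_seq, coord in _soft_clips(read):
            if len(clip_seq) < cfg.min_clip_len:
                continue
            prof = representative_unit(clip_seq, cfg)
            if not prof.informative:
                continue
            records.append(InformativeRead(
                sample=sample,
                chrom=read.reference_name,
                position=coord,
                unit=prof.best_unit,
                evidence_class=(EvidenceClass.CLIP_LEFT if side == "left"
                                else EvidenceClass.CLIP_RIGHT),
                repeat_count=prof.counts.get(prof.best_unit, 0),
                split_position=coord,
            ))

    informative = [p is not None and p.informative for p in profiles]
    if not any(informative):
        return records

    def mate_is_anchor(mate: pysam.AlignedSegment | None,
                       mate_profile: KmerProfile | None) -> bool:
        if mate is None or mate.is_unmapped:
            return False
        if mate.mapping_quality <= cfg.min_mapq:
            return False
        if mate_profile is not None and mate_profile.informative:
            return False
        if sinks is not None and sinks.overlaps(
                mate.reference_name, mate.reference_start, mate.reference_end):
            return False
        return True

    str_idx = 0 if informative[0] else 1
    if all(informative):
        # prefer the mate with higher repeat proportion as the STR read
        str_idx = max((0, 1), key=lambda i: profiles[i].best_proportion)
    str_profile = profiles[str_idx]
    mate = reads[1 - str_idx]
    mate_profile = profiles[1 - str_idx]

    if not all(informative) and mate_is_anchor(mate, mate_profile):
        contig = mate.reference_name
        clen = contig_lengths.get(contig, 2**31)
        records.append(InformativeRead(
            sample=sample,
            chrom=contig,
            position=_anchor_position(mate, frag, clen),
            unit=str_profile.best_unit,
            evidence_class=EvidenceClass.ANCHORED,
            repeat_count=str_profile.counts.get(str_profile.best_unit, 0),
        ))
    else:
        records.append(InformativeRead(
            sample=sample,
            chrom=None,
            position=None,
            unit=str_profile.best_unit,
            evidence_class=EvidenceClass.UNPLACED,
            repeat_count=str_profile.counts.get(str_profile.best_unit, 0),
        ))
    return records


def extract_sample(
    alignment_path: str | Path,
    sinks: Iterable[SinkRegion] | SinkLookup,
    cfg: SweepConfig = DEFAULT_CONFIG,
    sample: str | None = None,
    fasta: str | Path | None = None,
    max_fragment_sample: int = 100_000,
    min_fragment_observations: int = MIN_FRAGMENT_OBSERVATIONS,
) -> tuple[FragmentStats, list[InformativeRead]]:
    """Full extraction pass for one sample's BAM/CRAM.

    Estimates fragment statistics, selects candidate reads, pairs them
    with their mates and emits anchored / unplaced / clip records.
    """
    path = Path(alignment_path)
    sample = sample or path.stem.split(".")[0]
    lookup = sinks if isinstance(sinks, SinkLookup) else SinkLookup(sinks)
    kwargs = {"reference_filename": str(fasta)} if fasta else {}

    with pysam.AlignmentFile(str(path), **kwargs) as bam:
        frag = estimate_fragment_stats(
            bam, max_sample=max_fragment_sample, cfg=cfg,
            min_observations=min_fragment_observations)

    contig_lengths: dict[str, int] = {}
    candidates: set[str] = set()
    with pysam.AlignmentFile(str(path), **kwargs) as bam:
        contig_lengths = dict(zip(bam.references, bam.lengths))
        for read in select_candidate_reads(bam, lookup, cfg):
            candidates.add(read.query_name)

    # second pass: gather both mates of every candidate template
    pairs: dict[str, list[pysam.AlignedSegment | None]] = {}
    with pysam.AlignmentFile(str(path), **kwargs) as bam:
        for read in bam.fetch(until_eof=True):
            if not _is_primary(read) or read.query_name not in candidates:
                continue
            slot = pairs.setdefault(read.query_name, [None, None])
            slot[1 if read.is_read2 else 0] = read

    records: list[InformativeRead] = []
    for name, (r1, r2) in pairs.items():
        p1 = representative_unit(r1.query_sequence, cfg) if r1 is not None and r1.query_sequence else None
        p2 = representative_unit(r2.query_sequence, cfg) if r2 is not None and r2.query_sequence else None
        records.extend(classify_and_place(
            (r1, r2), p1, p2, frag, cfg,
            sinks=lookup, sample=sample, contig_lengths=contig_lengths))
    return frag, records


_IO_HEADER = ["sample", "chrom", "position", "unit", "class", "repeat_count",
              "split_position"]
_SENTINEL = "."


def write_records(records: Iterable[InformativeRead], path: str | Path) -> None:
    """Write evidence records as gzipped TSV, sorted by (unit, chrom, position)."""
    rows = sorted(
        records,
        key=lambda r: (r.unit, r.chrom or "", -1 if r.position is None else r.position),
    )
    with gzip.open(path, "wt") as fh:
        fh.write("\t".join(_IO_HEADER) + "\n")
        for r in rows:
            fh.write("\t".join([
                r.sample,
                r.chrom if r.chrom is not None else _SENTINEL,
                str(r.position) if r.position is not None else _SENTINEL,
                r.unit,
                r.evidence_class.value,
                str(r.repeat_count),
                str(r.split_position) if r.split_position is not None else _SENTINEL,
            ]) + "\n")


def read_records(path: str | Path) -> list[InformativeRead]:
    records = []
    with gzip.open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _IO_HEADER:
            raise ValueError(f"{path}:1: bad header {header}")
        for lineno, line in enumerate(fh, 2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_IO_HEADER):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(_IO_HEADER)} fields, got {len(fields)}")
            try:
                records.append(InformativeRead(
                    sample=fields[0],
                    chrom=None if fields[1] == _SENTINEL else fields[1],
                    position=None if fields[2] == _SENTINEL else int(fields[2]),
                    unit=fields[3],
                    evidence_class=EvidenceClass(fields[4]),
                    repeat_count=int(fields[5]),
                    split_position=None if fields[6] == _SENTINEL else int(fields[6]),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records
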