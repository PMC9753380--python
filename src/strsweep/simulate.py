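"""Synthetic data generation and evaluation metrics.

The simulator builds a reference contig carrying a short seed repeat
tract, donor haplotypes that extend the tract by a chosen number of
inserted repeat bases, and paired-end reads from those haplotypes. A
rule-based aligner emulation then produces a coordinate-sorted, indexed
BAM that reproduces the alignment signatures real aligners leave around
repeat expansions:

* reads wholly outside the insertion align perfectly;
* reads straddling an insertion edge are soft-clipped at the insertion
  point;
* small insertions that fit inside a read with enough anchored flank
  are represented as an ``I`` CIGAR operation;
* reads wholly inside the inserted repeat are emitted unmapped (or, when
  a same-unit sink exists elsewhere, mapped there with MAPQ 0).

Rule-based emulation keeps every downstream test hermetic and exactly
reproducible from the truth record; externally aligned BAMs can be
substituted wherever a BAM path is accepted.

Evaluation metrics (``position_error``, ``locus_found``) score reported
locus bounds against the planted truth interval.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .config import SweepConfig, DEFAULT_CONFIG
from .discovery import LocusBounds
from .kmers import canonical_rotation, revcomp
from .sinks import SinkRegion

# aligner-emulation rule thresholds (bp)
MIN_ALIGN = 20        # smallest flank that still anchors an alignment
INDEL_ANCHOR = 20     # flank needed on each side to call an insertion op
PERFECT_MAPQ = 60
SINK_MAPQ = 0
MAX_PROPER_TLEN = 2000


@dataclass
class SimTruth:
    """Complete description of one simulated sample; regenerating from it
    reproduces the reference, haplotypes, reads and BAM."""

    unit: str
    allele1_bp: int
    allele2_bp: int
    depth: float = 30.0
    read_length: int = 150
    fragment_mean: float = 400.0
    fragment_sd: float = 50.0
    seed: int = 0
    chrom: str = "sim1"
    contig_length: int = 20_000
    insertion_point: int | None = None
    seed_copies: int = 10
    background_seed: int | None = None
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.allele1_bp, self.allele2_bp) < 0:
            raise ValueError("allele sizes must be >= 0")
        if self.contig_length < 10 * self.fragment_mean:
            raise ValueError("contig must be >= 10 fragment lengths")
        self.unit = canonical_rotation(self.unit)

    @property
    def truth_interval(self) -> tuple[int, int]:
        """Reference coordinates of the seed repeat tract, half-open."""
        tract = self.seed_copies * len(self.unit)
        t1 = self.insertion_point if self.insertion_point is not None else (
            self.contig_length // 2)
        return t1 - tract, t1


def _random_flank(rng: np.random.Generator, length: int, unit: str,
                  max_tries: int = 50) -> str:
    """Random ACGT sequence containing no tract of >= 3 unit copies
    (checked over all rotations of the unit and its reverse complement)."""
    n = len(unit)
    # random sequence cannot avoid short homopolymer runs; for 1 bp units
    # only tracts comparable to a scoring window are excluded
    copies = 3 if n > 1 else 8
    forbidden = {(unit[i:] + unit[:i]) * copies for i in range(n)}
    rc = revcomp(unit)
    forbidden |= {(rc[i:] + rc[:i]) * copies for i in range(n)}
    for _ in range(max_tries):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if not any(f in seq for f in forbidden):
            return seq
    raise RuntimeError(f"could not generate a flank free of {unit} tracts")


def _repeat_bases(unit: str, n_bases: int) -> str:
    reps = unit * (n_bases // len(unit) + 1)
    return reps[:n_bases]


def make_reference_with_expansion(
    truth: SimTruth,
) -> tuple[str, tuple[str, str]]:
    """Build the reference contig and the two donor haplotypes.

    The reference carries ``seed_copies`` perfect copies of the unit
    ending at the insertion point; each donor haplotype extends the
    tract by ``allele{1,2}_bp`` bases of perfect repeat. Flanks are
    seeded random sequence free of incidental unit tracts.
    """
    rng = np.random.default_rng(
        truth.background_seed if truth.background_seed is not None else truth.seed)
    tract = _repeat_bases(truth.unit, truth.seed_copies * len(truth.unit))
    t0, t1 = truth.truth_interval
    if truth.insertion_point is None:
        truth.insertion_point = t1
    left_len = t0
    right_len = truth.contig_length - t1
    if left_len < 0 or right_len < 0:
        raise ValueError("insertion point outside contig")
    flank_left = _random_flank(rng, left_len, truth.unit)
    flank_right = _random_flank(rng, right_len, truth.unit)
    reference = flank_left + tract + flank_right
    haps = tuple(
        reference[:t1] + _repeat_bases(truth.unit, allele) + reference[t1:]
        for allele in (truth.allele1_bp, truth.allele2_bp)
    )
    return reference, haps


@dataclass
class SimReadPair:
    name: str
    hap: int            # 0 or 1; which donor haplotype
    start: int          # fragment start, donor coordinates
    fragment_length: int
    r1: str             # reference-forward sequence of the leftmost mate
    r2: str             # reference-forward sequence of the rightmost mate


def simulate_read_pairs(
    haplotypes: Sequence[str], truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> list[SimReadPair]:
    """Draw error-free paired-end fragments uniformly along each haplotype.

    Fragment lengths are Normal(fragment_mean, fragment_sd), truncated
    to [2 x read_length, 3 x fragment_mean]; each haplotype is sequenced
    to half the requested total depth. Optionally applies uniform
    substitution errors at ``truth.error_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    if truth.depth <= 0:
        return []
    rl = truth.read_length
    lo, hi = 2 * rl, 3 * truth.fragment_mean
    pairs: list[SimReadPair] = []
    for hap_idx, hap in enumerate(haplotypes):
        n_pairs = int(round((truth.depth / 2) * len(hap) / (2 * rl)))
        for i in range(n_pairs):
            flen = 0
            while not lo <= flen <= hi:
                flen = int(round(rng.normal(truth.fragment_mean, truth.fragment_sd)))
            start = int(rng.integers(0, max(1, len(hap) - flen)))
            r1 = hap[start:start + rl]
            r2 = hap[start + flen - rl:start + flen]
            if truth.error_rate > 0:
                r1 = _mutate(r1, truth.error_rate, rng)
                r2 = _mutate(r2, truth.error_rate, rng)
            pairs.append(SimReadPair(
                name=f"sim_h{hap_idx}_{i}", hap=hap_idx, start=start,
                fragment_length=flen, r1=r1, r2=r2))
    return pairs


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _place(start: int, end: int, ins_point: int, allele: int,
           sink: tuple[int, int] | None):
    """Map one read from donor to reference coordinates.

    Returns (ref_pos, cigartuples, mapq) or None for an unmapped read.
    """
    length = end - start
    if allele == 0 or end <= ins_point:
        return start, [(0, length)], PERFECT_MAPQ
    if start >= ins_point + allele:
        return start - allele, [(0, length)], PERFECT_MAPQ
    left_anchor = max(0, ins_point - start)
    right_anchor = max(0, end - (ins_point + allele))
    inside = length - left_anchor - right_anchor
    if inside == allele and left_anchor >= INDEL_ANCHOR and right_anchor >= INDEL_ANCHOR:
        return start, [(0, left_anchor), (1, allele), (0, right_anchor)], PERFECT_MAPQ
    if left_anchor >= right_anchor and left_anchor >= MIN_ALIGN:
        return start, [(0, left_anchor), (4, length - left_anchor)], PERFECT_MAPQ
    if right_anchor > left_anchor and right_anchor >= MIN_ALIGN:
        return ins_point, [(4, length - right_anchor), (0, right_anchor)], PERFECT_MAPQ
    if sink is not None:
        return sink[0], [(0, length)], SINK_MAPQ
    return None


def _ref_span(cigar: Iterable[tuple[int, int]]) -> int:
    return sum(l for op, l in cigar if op in (0, 2))


def emulate_alignment(
    pairs: Sequence[SimReadPair],
    reference: str,
    truth: SimTruth,
    out_bam: str | Path,
    sinks: Sequence[SinkRegion] | None = None,
) -> Path:
    """Write a coordinate-sorted, indexed BAM from simulated pairs.

    Unmapped reads with a mapped mate are stored at the mate's position
    (standard aligner convention); mateless unmapped pairs sort to the
    end of the file. Sequences are stored reference-forward.
    """
    out_bam = Path(out_bam)
    alleles = (truth.allele1_bp, truth.allele2_bp)
    ins_point = truth.insertion_point if truth.insertion_point is not None else (
        truth.truth_interval[1])
    sink = None
    if sinks:
        same_unit = [s for s in sinks if s.unit == truth.unit]
        if same_unit:
            biggest = max(same_unit, key=lambda s: s.end - s.start)
            sink = (biggest.start, biggest.end)

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": truth.chrom, "LN": len(reference)}]}
    tmp = out_bam.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(tmp), "wb", header=header) as bam:
        for pair in pairs:
            allele = alleles[pair.hap]
            rl = truth.read_length
            s1, e1 = pair.start, pair.start + rl
            s2, e2 = pair.start + pair.fragment_length - rl, pair.start + pair.fragment_length
            p1 = _place(s1, e1, ins_point, allele, sink)
            p2 = _place(s2, e2, ins_point, allele, sink)
            segs = []
            for idx, (seq, placement, is_r2) in enumerate(
                    ((pair.r1, p1, False), (pair.r2, p2, True))):
                a = pysam.AlignedSegment()
                a.query_name = pair.name
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                a.is_paired = True
                a.is_read1 = not is_r2
                a.is_read2 = is_r2
                a.is_reverse = is_r2 and placement is not None
                if placement is None:
                    a.is_unmapped = True
                    a.mapping_quality = 0
                else:
                    pos, cigar, mapq = placement
                    a.reference_id = 0
                    a.reference_start = pos
                    a.cigartuples = cigar
                    a.mapping_quality = mapq
                    a.set_tag("NM", 0 if mapq == PERFECT_MAPQ else len(seq) // 4)
                segs.append(a)
            a1, a2 = segs
            for a, mate, mate_placed in ((a1, a2, p2), (a2, a1, p1)):
                if mate_placed is None:
                    a.mate_is_unmapped = True
                else:
                    a.next_reference_id = 0
                    a.next_reference_start = mate_placed[0]
                    a.mate_is_reverse = mate.is_reverse
                if a.is_unmapped and mate_placed is not None:
                    # convention: park unmapped read at its mate's position
                    a.reference_id = 0
                    a.reference_start = mate_placed[0]
            if p1 is not None and p2 is not None:
                left = min(p1[0], p2[0])
                right = max(p1[0] + _ref_span(p1[1]), p2[0] + _ref_span(p2[1]))
                tlen = right - left
                proper = (tlen <= MAX_PROPER_TLEN
                          and min(p1[2], p2[2]) >= PERFECT_MAPQ)
                a1.template_length = tlen
                a2.template_length = -tlen
                a1.is_proper_pair = proper
                a2.is_proper_pair = proper
            bam.write(a1)
            bam.write(a2)
    pysam.sort("-o", str(out_bam), str(tmp))
    tmp.unlink()
    pysam.index(str(out_bam))
    return out_bam


def simulate_sample(
    truth: SimTruth,
    out_prefix: str | Path,
    sinks: Sequence[SinkRegion] | None = None,
    reference: str | None = None,
    haplotypes: tuple[str, str] | None = None,
    write_reference: bool = True,
) -> dict[str, Path]:
    """Run the full simulator for one sample.

    Writes ``<prefix>.fasta`` (+ .fai), ``<prefix>.bam`` (+ .bai) and
    ``<prefix>.truth.tsv``; returns the paths. A pre-built reference and
    haplotypes may be supplied so cohort samples share one contig.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if reference is None or haplotypes is None:
        reference, haplotypes = make_reference_with_expansion(truth)
    elif truth.insertion_point is None:
        truth.insertion_point = truth.truth_interval[1]
    paths = {"bam": out_prefix.with_suffix(".bam"),
             "fasta": out_prefix.with_suffix(".fasta"),
             "truth": out_prefix.with_suffix(".truth.tsv")}
    if write_reference:
        with open(paths["fasta"], "w") as fh:
            fh.write(f">{truth.chrom}\n")
            for i in range(0, len(reference), 80):
                fh.write(reference[i:i + 80] + "\n")
        pysam.faidx(str(paths["fasta"]))
    pairs = simulate_read_pairs(haplotypes, truth)
    emulate_alignment(pairs, reference, truth, paths["bam"], sinks=sinks)
    write_truth(truth, paths["truth"])
    return paths


def write_truth(truth: SimTruth, path: str | Path) -> None:
    fields = dataclasses.asdict(truth)
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")
        fh.write("\t".join("." if v is None else str(v)
                           for v in fields.values()) + "\n")


def read_truth(path: str | Path) -> SimTruth:
    with open(path) as fh:
        names = fh.readline().rstrip("\n").split("\t")
        values = fh.readline().rstrip("\n").split("\t")
    kwargs: dict = {}
    types = {f.name: f.type for f in dataclasses.fields(SimTruth)}
    for name, value in zip(names, values):
        if value == ".":
            kwargs[name] = None
        elif "int" in str(types[name]):
            kwargs[name] = int(value)
        elif "float" in str(types[name]):
            kwargs[name] = float(value)
        else:
            kwargs[name] = value
    return SimTruth(**kwargs)


def calibration_grid(
    allele_sizes: Sequence[int],
    workdir: str | Path,
    unit: str = "CAG",
    seed: int = 0,
    depth: float = 30.0,
    contig_length: int = 20_000,
    cfg: SweepConfig = DEFAULT_CONFIG,
):
    """Simulate a heterozygous expansion grid and collect locus evidence.

    One sample per allele size (reference allele + expansion of the
    given size) on a shared contig. Evidence is gathered at the true
    locus bounds, so the grid isolates the evidence -> size relationship
    from locus-discovery noise. Returns (frag, [(allele_bp, evidence)]).
    """
    from .genotype import collect_locus_evidence
    from .pipeline import process_sample

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    points = []
    frag = None
    for i, allele in enumerate(allele_sizes):
        truth = SimTruth(unit=unit, allele1_bp=0, allele2_bp=int(allele),
                         depth=depth, contig_length=contig_length,
                         seed=seed + i + 1, background_seed=seed)
        paths = simulate_sample(truth, workdir / f"grid{i}")
        evidence = process_sample(paths["bam"], sample=f"grid{i}", cfg=cfg)
        frag = evidence.frag
        t0, t1 = truth.truth_interval
        locus = LocusBounds(chrom=truth.chrom, left=t1, right=t1,
                            unit=canonical_rotation(unit),
                            n_support_per_sample={f"grid{i}": cfg.min_support})
        import pysam

        with pysam.AlignmentFile(str(paths["bam"])) as bam:
            summary = collect_locus_evidence(
                bam, locus, evidence.records, evidence.frag, cfg)
        unplaced = sum(
            1 for r in evidence.records
            if r.evidence_class.value == "UNPLACED" and r.unit == locus.unit)
        summary.unplaced_pairs = unplaced
        points.append((float(allele), summary))
    return frag, points


NOT_FOUND = None


def position_error(call: LocusBounds,
                   truth_interval: tuple[str, int, int]) -> int | None:
    """Worst-side distance (bp) from a call's bounds to the truth interval.

    Each bound scores 0 when it lies within the truth interval and the
    distance to the nearer truth edge otherwise; the two sides are
    scored separately and the maximum returned. Calls on a different
    contig return the not-found sentinel (None).
    """
    chrom, start, end = truth_interval
    if call.chrom != chrom:
        return NOT_FOUND

    def side(bound: int) -> int:
        if start <= bound <= end:
            return 0
        return min(abs(bound - start), abs(bound - end))

    return max(side(call.left), side(call.right))


def locus_found(
    calls: Iterable[LocusBounds],
    truth_interval: tuple[str, int, int],
    unit: str,
    cfg: SweepConfig = DEFAULT_CONFIG,
) -> bool:
    """True when some call has the right canonical unit within
    ``cfg.found_window`` bp of the truth interval."""
    chrom, start, end = truth_interval
    want = canonical_rotation(unit)
    pad = cfg.found_window
    for call in calls:
        if call.chrom != chrom or canonical_rotation(call.unit) != want:
            continue
        if call.left <= end + pad and call.right >= start - pad:
            return True
    return False
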