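"""Per-sample allele-size estimation at discovered loci.

A second, targeted pass of the alignment gathers the read classes that
carry size information (Fig-style evidence ladder):

* spanning reads — alignments fully covering the locus; their mean net
  indel size estimates alleles shorter than the read length;
* anchored + overlapping reads — their summed repeat-unit copies grow
  with allele size up to roughly the median fragment length;
* unplaced pairs — pairs with no usable position; their count grows
  with allele size beyond the median fragment length.

Two ordinary least-squares models, calibrated on simulated expansions of
known size, convert the depth-normalised predictors into base pairs of
inserted repeat. The small-allele regime uses summed repeat counts, the
large-allele regime unplaced-pair counts, with the crossover at the
sample's median fragment length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .config import SweepConfig, DEFAULT_CONFIG
from .discovery import LocusBounds
from .extract import (EvidenceClass, FragmentStats, InformativeRead,
                      _is_primary)
from .kmers import representative_unit


@dataclass
class EvidenceSummary:
    """Read-evidence counts for one sample at one locus."""

    locus: LocusBounds
    anchored_pairs: int = 0
    unplaced_pairs: int = 0
    spanning_reads: int = 0
    spanning_pairs: int = 0
    overlapping_reads: int = 0
    sum_str_counts: int = 0
    local_depth: float = 0.0
    spanning_indels: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class AlleleModel:
    """Two-regime linear map from read evidence to inserted bp."""

    small_intercept: float
    small_slope: float
    large_intercept: float
    large_slope: float
    crossover: float  # bp; normally the median fragment length

    def predict_small(self, norm_str_counts: float) -> float:
        return max(0.0, self.small_intercept + self.small_slope * norm_str_counts)

    def predict_large(self, norm_unplaced: float) -> float:
        return max(0.0, self.large_intercept + self.large_slope * norm_unplaced)


class Zygosity:
    HET = "HET"
    HOM_OR_HEMI = "HOM_OR_HEMI"
    UNKNOWN = "UNKNOWN"


@dataclass
class GenotypeCall:
    locus: LocusBounds
    allele1_bp: float | None
    allele2_bp: float | None
    evidence: EvidenceSummary
    zygosity_hint: str = Zygosity.UNKNOWN

    def __post_init__(self) -> None:
        if (self.allele1_bp is not None and self.allele2_bp is not None
                and self.allele1_bp > self.allele2_bp):
            raise ValueError("allele1_bp must be <= allele2_bp")


def _net_indel(read: pysam.AlignedSegment) -> int:
    ins = sum(l for op, l in read.cigartuples if op == 1)
    dels = sum(l for op, l in read.cigartuples if op == 2)
    return ins - dels


def _mean_depth(bam: pysam.AlignmentFile, chrom: str, start: int, end: int) -> float:
    """Mean aligned depth over [start, end) from overlap lengths."""
    start = max(0, start)
    end = min(end, bam.get_reference_length(chrom))
    if end <= start:
        return 0.0
    total = 0
    for read in bam.fetch(chrom, start, end):
        if not _is_primary(read) or read.is_unmapped:
            continue
        total += max(0, min(read.reference_end, end) - max(read.reference_start, start))
    return total / (end - start)


def collect_locus_evidence(
    alignment: pysam.AlignmentFile,
    locus: LocusBounds,
    records: Sequence[InformativeRead],
    frag: FragmentStats,
    cfg: SweepConfig = DEFAULT_CONFIG,
    unplaced_pairs: int = 0,
) -> EvidenceSummary:
    """Second-pass evidence collection for one locus in one sample.

    ``records`` are the sample's extraction records; anchored and clip
    records within the clustering window of the locus are assigned to it.
    ``unplaced_pairs`` is supplied by the caller (unplaced records carry
    no position; see :func:`assign_unplaced`).
    """
    if locus.chrom not in alignment.references:
        raise ValueError(f"locus contig {locus.chrom!r} absent from alignment")
    ev = EvidenceSummary(locus=locus, unplaced_pairs=unplaced_pairs)
    slack = cfg.cluster_slack(frag.p98)

    for r in records:
        if r.unit != locus.unit or r.position is None or r.chrom != locus.chrom:
            continue
        if locus.left - slack <= r.position <= locus.right + slack:
            if r.evidence_class is EvidenceClass.ANCHORED:
                ev.anchored_pairs += 1
                ev.sum_str_counts += r.repeat_count

    left, right = locus.left, locus.right
    seen_templates: set[str] = set()
    fetch_start = max(0, left - frag.median)
    fetch_end = min(alignment.get_reference_length(locus.chrom), right + frag.median)
    for read in alignment.fetch(locus.chrom, fetch_start, fetch_end):
        if not _is_primary(read) or read.is_unmapped:
            continue
        covers = read.reference_start < left and read.reference_end > right
        if covers and read.mapping_quality >= cfg.min_mapq:
            has_clip = any(op == 4 for op, _ in read.cigartuples)
            if not has_clip:
                ev.spanning_reads += 1
                ev.spanning_indels.append(float(_net_indel(read)))
        # overlapping: informative read aligned inside the locus
        if (read.reference_start >= left and read.reference_end <= max(right, left + 1)
                and read.query_sequence):
            prof = representative_unit(read.query_sequence, cfg)
            if prof.informative and prof.best_unit == locus.unit:
                ev.overlapping_reads += 1
                ev.sum_str_counts += prof.counts.get(prof.best_unit, 0)
        # spanning pairs: fragment covers the locus, both mates well mapped
        if (read.is_proper_pair and not read.mate_is_unmapped
                and read.mapping_quality >= cfg.min_mapq
                and read.template_length > 0
                and read.query_name not in seen_templates):
            frag_start = read.reference_start
            frag_end = read.reference_start + read.template_length
            if frag_start < left and frag_end > right:
                ev.spanning_pairs += 1
                seen_templates.add(read.query_name)

    ev.local_depth = _mean_depth(alignment, locus.chrom,
                                 left - frag.median, right + frag.median)
    return ev


def assign_unplaced(
    records: Sequence[InformativeRead],
    loci: Sequence[LocusBounds],
    anchored_support: dict[int, int],
) -> dict[int, int]:
    """Assign each unplaced record to the same-unit locus with the most
    anchored support in this sample; ties leave the record unassigned.

    ``anchored_support`` maps locus index -> anchored pair count.
    Returns locus index -> number of unplaced pairs assigned.
    """
    by_unit: dict[str, list[int]] = {}
    for i, locus in enumerate(loci):
        by_unit.setdefault(locus.unit, []).append(i)
    out: dict[int, int] = {i: 0 for i in range(len(loci))}
    for r in records:
        if r.evidence_class is not EvidenceClass.UNPLACED:
            continue
        candidates = by_unit.get(r.unit, [])
        if not candidates:
            continue
        best = max(anchored_support.get(i, 0) for i in candidates)
        winners = [i for i in candidates if anchored_support.get(i, 0) == best]
        if len(winners) == 1:
            out[winners[0]] += 1
    return out


def estimate_small_allele(spanning_read_indels: Sequence[float]) -> float | None:
    """Mean net indel size over spanning reads; None without evidence."""
    if not spanning_read_indels:
        return None
    return float(np.mean(spanning_read_indels))


def calibrate_allele_model(
    simulated_truth: Iterable[tuple[float, EvidenceSummary]],
    frag: FragmentStats,
    cfg: SweepConfig = DEFAULT_CONFIG,
) -> AlleleModel:
    """Fit the two-regime model on simulations with known allele sizes.

    Alleles at or below the median fragment length train the small
    regime (depth-normalised summed repeat counts); larger alleles train
    the large regime (depth-normalised unplaced pairs). Ordinary least
    squares in each regime.
    """
    small_x, small_y, large_x, large_y = [], [], [], []
    for allele_bp, ev in simulated_truth:
        depth_factor = max(ev.local_depth, 1e-9) / cfg.depth_baseline
        if allele_bp <= frag.median:
            small_x.append(ev.sum_str_counts / depth_factor)
            small_y.append(allele_bp)
        else:
            large_x.append(ev.unplaced_pairs / depth_factor)
            large_y.append(allele_bp)
    model_params = []
    for xs, ys, regime in ((small_x, small_y, "small"), (large_x, large_y, "large")):
        x = np.asarray(xs, dtype=float)
        y = np.asarray(ys, dtype=float)
        if x.size < 2 or np.ptp(x) == 0:
            raise ValueError(f"degenerate design in {regime} regime "
                             f"(n={x.size}, zero-variance predictor)")
        slope, intercept = np.polyfit(x, y, 1)
        model_params.append((float(intercept), float(slope)))
    (si, ss), (li, ls) = model_params
    return AlleleModel(small_intercept=si, small_slope=ss,
                       large_intercept=li, large_slope=ls,
                       crossover=float(frag.median))


# Coefficients from the package's built-in simulator calibration
# (read length 150 bp, fragment Normal(400, 50), depth 30x, heterozygous
# 30-point grid over 0-1800 bp, seed 20260929); regenerate with
# strsweep.simulate.calibration_grid + calibrate_allele_model.
DEFAULT_ALLELE_MODEL = AlleleModel(
    small_intercept=42.449,
    small_slope=0.19939,
    large_intercept=394.137,
    large_slope=16.6348,
    crossover=402.0,
)


def estimate_allele_sizes(
    evidence: EvidenceSummary,
    model: AlleleModel,
    frag: FragmentStats,
    cfg: SweepConfig = DEFAULT_CONFIG,
) -> GenotypeCall:
    """Convert one locus's evidence into two allele-size estimates.

    The short allele comes from spanning-read indels when available. The
    long allele starts from the small-regime prediction and switches to
    the large regime when unplaced pairs exist and either regime places
    the allele beyond the fragment median: summed repeat counts saturate
    near the median fragment length, so requiring the small-regime
    prediction alone to clear the crossover would strand genuinely large
    alleles in the saturated regime. Estimates are floored at zero and
    ordered.
    """
    depth_factor = max(evidence.local_depth, 1e-9) / cfg.depth_baseline
    allele1 = estimate_small_allele(evidence.spanning_indels)

    allele2 = model.predict_small(evidence.sum_str_counts / depth_factor)
    if evidence.unplaced_pairs > 0:
        large = model.predict_large(evidence.unplaced_pairs / depth_factor)
        if large >= model.crossover or allele2 >= model.crossover:
            allele2 = large

    if allele1 is not None and allele1 > allele2:
        allele1, allele2 = allele2, allele1

    expansion_evidence = (evidence.anchored_pairs + evidence.unplaced_pairs) > 0
    if evidence.spanning_reads == 0 and evidence.spanning_pairs <= 2 and expansion_evidence:
        zyg = Zygosity.HOM_OR_HEMI
    elif allele1 is not None and expansion_evidence:
        zyg = Zygosity.HET
    else:
        zyg = Zygosity.UNKNOWN

    return GenotypeCall(locus=evidence.locus, allele1_bp=allele1,
                        allele2_bp=allele2, evidence=evidence,
                        zygosity_hint=zyg)


def call_sample(
    alignment_path: str | Path,
    loci: Sequence[LocusBounds],
    records: Sequence[InformativeRead],
    frag: FragmentStats,
    cfg: SweepConfig = DEFAULT_CONFIG,
    model: AlleleModel | None = None,
    fasta: str | Path | None = None,
) -> list[GenotypeCall]:
    """Genotype one sample at a shared set of locus bounds."""
    model = model or DEFAULT_ALLELE_MODEL
    kwargs = {"reference_filename": str(fasta)} if fasta else {}
    calls: list[GenotypeCall] = []
    with pysam.AlignmentFile(str(alignment_path), **kwargs) as bam:
        summaries = [
            collect_locus_evidence(bam, locus, records, frag, cfg)
            for locus in loci
        ]
    anchored_support = {i: s.anchored_pairs for i, s in enumerate(summaries)}
    unplaced = assign_unplaced(records, loci, anchored_support)
    for i, summary in enumerate(summaries):
        summary.unplaced_pairs = unplaced.get(i, 0)
        calls.append(estimate_allele_sizes(summary, model, frag, cfg))
    return calls


_GT_HEADER = ["chrom", "left", "right", "unit", "allele1_bp", "allele2_bp",
              "spanning_reads", "spanning_pairs", "anchored_pairs",
              "unplaced_pairs", "sum_str_counts", "local_depth", "zygosity_hint"]


def write_genotypes(calls: Iterable[GenotypeCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GT_HEADER) + "\n")
        for c in calls:
            ev = c.evidence
            fh.write("\t".join([
                c.locus.chrom, str(c.locus.left), str(c.locus.right), c.locus.unit,
                "." if c.allele1_bp is None else f"{c.allele1_bp:.1f}",
                "." if c.allele2_bp is None else f"{c.allele2_bp:.1f}",
                str(ev.spanning_reads), str(ev.spanning_pairs),
                str(ev.anchored_pairs), str(ev.unplaced_pairs),
                str(ev.sum_str_counts), f"{ev.local_depth:.3f}",
                c.zygosity_hint,
            ]) + "\n")
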