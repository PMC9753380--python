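"""End-to-end orchestration: extract -> merge -> call -> outlier.

Thin glue over the stage modules, shared by the CLI, the tests and the
reproduction script. Each helper takes and returns plain stage objects
so individual stages remain independently usable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import SweepConfig, DEFAULT_CONFIG
from .discovery import LocusBounds, discover_loci, joint_merge
from .extract import FragmentStats, InformativeRead, extract_sample
from .genotype import AlleleModel, GenotypeCall, call_sample
from .sinks import SinkRegion


@dataclass
class SampleEvidence:
    sample: str
    bam: Path
    frag: FragmentStats
    records: list[InformativeRead]


def process_sample(
    bam: str | Path,
    sinks: Sequence[SinkRegion] = (),
    cfg: SweepConfig = DEFAULT_CONFIG,
    sample: str | None = None,
    fasta: str | Path | None = None,
    min_fragment_observations: int = 50,
) -> SampleEvidence:
    """Extraction stage for one sample.

    The fragment-observation floor defaults low here because simulated
    contigs are small; production extraction via the CLI keeps the
    stricter default.
    """
    bam = Path(bam)
    name = sample or bam.stem.split(".")[0]
    frag, records = extract_sample(
        bam, sinks, cfg, sample=name, fasta=fasta,
        min_fragment_observations=min_fragment_observations)
    return SampleEvidence(sample=name, bam=bam, frag=frag, records=records)


def discover_cohort(
    samples: Sequence[SampleEvidence],
    cfg: SweepConfig = DEFAULT_CONFIG,
) -> list[LocusBounds]:
    """Joint locus discovery over any number of extracted samples."""
    return joint_merge(
        {s.sample: s.records for s in samples},
        {s.sample: s.frag for s in samples},
        cfg,
    )


def discover_single(
    evidence: SampleEvidence, cfg: SweepConfig = DEFAULT_CONFIG
) -> list[LocusBounds]:
    return discover_loci(evidence.records, evidence.frag, cfg)


def genotype_cohort(
    samples: Sequence[SampleEvidence],
    loci: Sequence[LocusBounds],
    cfg: SweepConfig = DEFAULT_CONFIG,
    model: AlleleModel | None = None,
    fasta: str | Path | None = None,
) -> dict[str, list[GenotypeCall]]:
    """Genotype every sample at the shared loci."""
    return {
        s.sample: call_sample(s.bam, loci, s.records, s.frag, cfg,
                              model=model, fasta=fasta)
        for s in samples
    }


def genotype_frame(calls: Sequence[GenotypeCall]) -> pd.DataFrame:
    """Genotype calls as the tabular form the outlier stage consumes."""
    rows = []
    for c in calls:
        ev = c.evidence
        rows.append({
            "chrom": c.locus.chrom, "left": c.locus.left,
            "right": c.locus.right, "unit": c.locus.unit,
            "allele1_bp": c.allele1_bp, "allele2_bp": c.allele2_bp,
            "spanning_reads": ev.spanning_reads,
            "spanning_pairs": ev.spanning_pairs,
            "anchored_pairs": ev.anchored_pairs,
            "unplaced_pairs": ev.unplaced_pairs,
            "sum_str_counts": ev.sum_str_counts,
            "local_depth": ev.local_depth,
            "zygosity_hint": c.zygosity_hint,
        })
    return pd.DataFrame(rows)


def cohort_genotype_tables(
    genotypes: Mapping[str, Sequence[GenotypeCall]],
) -> dict[str, pd.DataFrame]:
    return {s: genotype_frame(calls) for s, calls in genotypes.items()}
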