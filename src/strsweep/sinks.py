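"""Reference index of large perfect STR tracts ("sinks").

Long uninterrupted repeat tracts in the reference attract mismapped
repetitive reads from elsewhere in the genome; recording them up front
lets the extraction stage treat any read aligned to one as a candidate
with an unreliable position. The scan slides fixed-size windows along
each contig, scores each window with the same k-mer machinery used on
reads, and merges qualifying same-unit windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .config import SweepConfig, DEFAULT_CONFIG
from .kmers import representative_unit


@dataclass
class SinkRegion:
    """A merged run of repeat-dominated reference windows (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    unit: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("SinkRegion requires start < end")


def window_repeat_fraction(
    seq: str, cfg: SweepConfig = DEFAULT_CONFIG
) -> tuple[str | None, float]:
    """Score one reference window; unit is None below the qualifying threshold."""
    profile = representative_unit(seq, cfg)
    if profile.informative:
        return profile.best_unit, profile.best_proportion
    return None, profile.best_proportion


def scan_contig(
    chrom: str, seq: str, cfg: SweepConfig = DEFAULT_CONFIG
) -> list[SinkRegion]:
    """Slide windows along one contig sequence and merge qualifying ones.

    The final window is evaluated at its natural (shorter) length with the
    same proportional threshold. Overlapping or abutting windows sharing a
    canonical unit merge into a single region; mixed-unit adjacency stays
    separate.
    """
    regions: list[SinkRegion] = []
    n = len(seq)
    for pos in range(0, n, cfg.window_slide):
        window = seq[pos:pos + cfg.window_size]
        if len(window) < cfg.min_k:
            break
        unit, _ = window_repeat_fraction(window, cfg)
        if unit is not None:
            end = pos + len(window)
            if regions and regions[-1].unit == unit and pos <= regions[-1].end:
                regions[-1].end = max(regions[-1].end, end)
            else:
                regions.append(SinkRegion(chrom, pos, end, unit))
    return regions


def build_sink_index(
    fasta_path: str | Path, cfg: SweepConfig = DEFAULT_CONFIG
) -> list[SinkRegion]:
    """Scan an indexed FASTA and return all sink regions, sorted.

    Deterministic for a given reference and configuration. Requires a
    ``.fai`` index (create one with ``samtools faidx``).
    """
    fasta_path = Path(fasta_path)
    if not (fasta_path.with_suffix(fasta_path.suffix + ".fai").exists()):
        try:
            pysam.faidx(str(fasta_path))
        except Exception as exc:  # pragma: no cover - permission/format issues
            raise FileNotFoundError(
                f"{fasta_path} has no .fai index and indexing failed; "
                f"run 'samtools faidx {fasta_path}'"
            ) from exc
    regions: list[SinkRegion] = []
    with pysam.FastaFile(str(fasta_path)) as fa:
        for chrom in fa.references:
            regions.extend(scan_contig(chrom, fa.fetch(chrom), cfg))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def write_bed(regions: Iterable[SinkRegion], path: str | Path) -> None:
    """Write sinks as BED4 (chrom, start, end, unit)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.unit}\n")


def read_bed(path: str | Path) -> list[SinkRegion]:
    regions = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{i}: expected BED4, got {line!r}")
            regions.append(SinkRegion(fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return regions


class SinkLookup:
    """Interval lookup over sink regions, per contig."""

    def __init__(self, regions: Iterable[SinkRegion]):
        from intervaltree import IntervalTree

        self._trees: dict[str, "IntervalTree"] = {}
        for r in regions:
            self._trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.unit)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, max(end, start + 1)))

    def regions_for_unit(self, unit: str) -> Iterator[tuple[str, int, int]]:
        for chrom, tree in self._trees.items():
            for iv in tree:
                if iv.data == unit:
                    yield chrom, iv.begin, iv.end
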