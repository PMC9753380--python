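"""Cohort-level outlier prioritisation of per-locus repeat counts.

Each sample's summed repeat count at a locus is normalised by local
sequencing depth, ``log2((sum_str_counts + 1) / local_depth)``, then
tested against the cohort: a z-score against the cohort median and
standard deviation, a one-sided upper-tail normal p-value, and a
Benjamini-Hochberg adjustment across all loci within each sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import SweepConfig, DEFAULT_CONFIG


@dataclass
class OutlierRecord:
    sample: str
    locus_key: tuple[str, int, int, str]  # (chrom, left, right, unit)
    sum_str_counts: int
    local_depth: float
    norm: float
    z: float
    p: float
    p_adj: float
    significant: bool


def normalize_count(sum_str_counts: float, local_depth: float) -> float:
    """Depth-normalised log2 repeat count: log2((count + 1) / depth)."""
    if local_depth <= 0:
        raise ValueError("local_depth must be positive; zero-depth entries "
                         "are treated as missing upstream")
    return math.log2((sum_str_counts + 1) / local_depth)


def outlier_test(
    norms_at_locus: Mapping[str, float],
    control_samples: Sequence[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-sample (z, p) at one locus against the cohort distribution.

    z uses the median and the n-1 standard deviation of the normalised
    counts; p is the one-sided upper-tail standard-normal probability.
    When ``control_samples`` is given, the median/SD come from those
    samples only (case-vs-controls conditioning); every sample is still
    scored. Degenerate loci (SD = 0) yield z = 0, p = 1 for all samples.
    Requires at least 3 conditioning samples.
    """
    cond = (list(control_samples) if control_samples is not None
            else list(norms_at_locus))
    values = np.array([norms_at_locus[s] for s in cond if s in norms_at_locus])
    if values.size < 3:
        raise ValueError(f"outlier test needs >= 3 samples, got {values.size}")
    med = float(np.median(values))
    sd = float(np.std(values, ddof=1))
    out: dict[str, tuple[float, float]] = {}
    for sample, x in norms_at_locus.items():
        if sd == 0.0:
            out[sample] = (0.0, 1.0)
        else:
            z = (x - med) / sd
            out[sample] = (z, float(norm.sf(z)))
    return out


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def run_outlier(
    genotype_tables: Mapping[str, pd.DataFrame],
    cfg: SweepConfig = DEFAULT_CONFIG,
    control_samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Outlier-test a jointly called cohort.

    ``genotype_tables`` maps sample name to its genotype table (columns
    chrom, left, right, unit, sum_str_counts, local_depth, …) — all
    samples must share the same loci. Zero-depth entries are treated as
    missing: excluded from the conditioning set and given no record.
    Returns one row per (sample, locus) with z, p, BH-adjusted p (within
    sample) and a significance flag at ``cfg.alpha``.
    """
    if not genotype_tables:
        raise ValueError("empty cohort")
    key_cols = ["chrom", "left", "right", "unit"]
    keys = None
    for sample, table in genotype_tables.items():
        sample_keys = set(map(tuple, table[key_cols].itertuples(index=False)))
        if keys is None:
            keys = sample_keys
        elif sample_keys != keys:
            missing = keys ^ sample_keys
            raise ValueError(
                f"sample {sample!r} was not called on the shared loci; "
                f"{len(missing)} mismatching loci, e.g. {sorted(missing)[:3]}")

    rows = []
    indexed = {
        s: t.set_index(key_cols) for s, t in genotype_tables.items()
    }
    for key in sorted(keys):
        norms: dict[str, float] = {}
        raw: dict[str, tuple[int, float]] = {}
        for sample, table in indexed.items():
            row = table.loc[key]
            depth = float(row["local_depth"])
            if depth <= 0:
                continue  # missing entry
            count = int(row["sum_str_counts"])
            raw[sample] = (count, depth)
            norms[sample] = normalize_count(count, depth)
        if len(norms) < 3:
            continue  # locus skipped; too few usable samples
        cond = None
        if control_samples is not None:
            cond = [s for s in control_samples if s in norms]
        for sample, (z, p) in outlier_test(norms, cond).items():
            count, depth = raw[sample]
            rows.append({
                "sample": sample, "chrom": key[0], "left": key[1],
                "right": key[2], "unit": key[3],
                "sum_str_counts": count, "local_depth": depth,
                "norm": norms[sample], "z": z, "p": p,
            })
    result = pd.DataFrame(rows)
    if result.empty:
        result["p_adj"] = []
        result["significant"] = []
        return result
    result["p_adj"] = np.nan
    for sample, idx in result.groupby("sample").groups.items():
        result.loc[idx, "p_adj"] = bh_adjust(result.loc[idx, "p"].tolist())
    result["significant"] = result["p_adj"] < cfg.alpha
    return result.sort_values(["sample", "chrom", "left"]).reset_index(drop=True)


def filter_candidates(
    outliers: pd.DataFrame,
    exclude_homopolymers: bool = False,
    exclude_beds: Iterable[str | Path] = (),
) -> pd.DataFrame:
    """Post-filters mirroring common prioritisation practice.

    Optionally removes homopolymer-unit loci and loci overlapping any
    interval in the given BED files (low-complexity regions, segmental
    duplications, ...).
    """
    from intervaltree import IntervalTree

    keep = pd.Series(True, index=outliers.index)
    if exclude_homopolymers:
        keep &= outliers["unit"].str.len() > 1
    trees: dict[str, IntervalTree] = {}
    for bed in exclude_beds:
        with open(bed) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                trees.setdefault(f[0], IntervalTree()).addi(int(f[1]), int(f[2]))
    if trees:
        def hits(row) -> bool:
            tree = trees.get(row["chrom"])
            return bool(tree and tree.overlap(row["left"], max(row["right"], row["left"] + 1)))
        keep &= ~outliers.apply(hits, axis=1)
    return outliers[keep].reset_index(drop=True)
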