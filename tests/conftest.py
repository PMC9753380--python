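"""Shared fixtures: tiny naive oracles and simulated samples."""

from __future__ import annotations

import pytest


def naive_canonical(unit: str) -> str:
    """Brute-force canonical rotation: enumerate, collapse homopolymers."""
    if len(set(unit)) == 1:
        return unit[0]
    rotations = [unit[i:] + unit[:i] for i in range(len(unit))]
    return sorted(rotations)[0]


def naive_counts(seq: str, k: int) -> dict[str, int]:
    """Slice/rotate/tally with explicit loops, independent of the package."""
    counts: dict[str, int] = {}
    i = 0
    while i + k <= len(seq):
        window = seq[i:i + k]
        if all(ch in "ACGT" for ch in window):
            unit = naive_canonical(window)
            step = k // len(unit) if len(unit) < k else 1
            counts[unit] = counts.get(unit, 0) + step
        i += k
    return counts


def naive_best_unit(seq: str, min_k: int = 2, max_k: int = 6):
    """(unit, proportion) by exhaustive scan over all k, spec tie-breaks."""
    best = None
    for k in range(min_k, max_k + 1):
        if k > len(seq):
            break
        for unit, count in naive_counts(seq, k).items():
            prop = count * len(unit) / len(seq)
            key = (-prop, len(unit), unit)
            if best is None or key < best[0]:
                best = (key, unit, prop)
    if best is None:
        return None, 0.0
    return best[1], best[2]


@pytest.fixture(scope="session")
def het600_sample(tmp_path_factory):
    """One simulated heterozygous 600 bp CAG expansion, fully processed."""
    import strsweep as s
    from strsweep.pipeline import process_sample

    truth = s.SimTruth(unit="CAG", allele1_bp=0, allele2_bp=600, seed=7)
    prefix = tmp_path_factory.mktemp("het600") / "het600"
    paths = s.simulate_sample(truth, prefix)
    evidence = process_sample(paths["bam"], sample="het600")
    return truth, paths, evidence
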