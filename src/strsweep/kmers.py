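"""Repeat-unit detection in read sequences.

Tandem repeats are found by counting *non-overlapping* k-mers for every
unit length k in [min_k, max_k]: the sequence is scanned k bp at a time
and each window is reduced to a rotation-canonical repeat unit (the
lexicographically smallest rotation) so that phase shifts caused by small
interruptions do not fragment the tally. Homopolymer-periodic windows
(e.g. ``AA``) collapse to the single base. A read is *informative* when
its best unit accounts for at least ``proportion_repeat`` of the read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import SweepConfig, DEFAULT_CONFIG

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMP = str.maketrans("ACGT", "TGCA")


class InvalidUnitError(ValueError):
    """Raised when a k-mer contains characters outside {A,C,G,T}."""


def canonical_rotation(unit: str) -> str:
    """Return the rotation-canonical form of a repeat unit.

    The canonical form is the lexicographically smallest rotation
    (A < C < G < T); a homopolymer-periodic unit collapses to its single
    base. Idempotent.

    Raises
    ------
    InvalidUnitError
        If the unit is empty, longer than 6 bp, or contains non-ACGT
        characters (callers skip such windows).
    """
    u = unit.upper()
    if not 1 <= len(u) <= 6:
        raise InvalidUnitError(f"unit length {len(u)} outside 1..6: {unit!r}")
    first = u[0]
    if u == first * len(u):
        if first not in _CODE:
            raise InvalidUnitError(f"non-ACGT character in {unit!r}")
        return first
    for ch in u:
        if ch not in _CODE:
            raise InvalidUnitError(f"non-ACGT character in {unit!r}")
    doubled = u + u
    return min(doubled[i:i + len(u)] for i in range(len(u)))


def encode_unit(unit: str) -> int:
    """Pack a 1-6 bp ACGT unit into an integer, 2 bits per base.

    A leading sentinel bit pair keeps leading-``A`` units distinct, so
    the encoding is injective across lengths.
    """
    code = 1
    for ch in unit:
        code = (code << 2) | _CODE[ch]
    return code


def decode_unit(code: int) -> str:
    """Inverse of :func:`encode_unit`."""
    out = []
    while code > 1:
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def count_nonoverlapping(seq: str, k: int) -> dict[str, int]:
    """Tally rotation-canonical k-mers at offsets 0, k, 2k, ...

    The trailing remainder shorter than k is ignored, as are windows
    containing non-ACGT characters. Homopolymer windows are credited to
    the single-base unit in base units (one ``AA`` window adds 2 copies
    of ``A``) so that ``count * len(unit)`` always equals the bases the
    unit accounts for.
    """
    counts: dict[str, int] = {}
    seq = seq.upper()
    for i in range(0, len(seq) - k + 1, k):
        window = seq[i:i + k]
        try:
            unit = canonical_rotation(window)
        except InvalidUnitError:
            continue
        counts[unit] = counts.get(unit, 0) + (k // len(unit) if len(unit) < k else 1)
    return counts


@dataclass
class KmerProfile:
    """Best repeat unit of a sequence and the fraction it accounts for."""

    read_length: int
    counts: dict[str, int] = field(default_factory=dict)
    best_unit: str | None = None
    best_proportion: float = 0.0
    informative: bool = False


def representative_unit(seq: str, cfg: SweepConfig = DEFAULT_CONFIG) -> KmerProfile:
    """Score a sequence for STR content across all unit lengths.

    Runs :func:`count_nonoverlapping` for every k in [min_k, max_k] and
    picks the unit covering the greatest proportion of the sequence
    (denominator: full sequence length). Ties are broken toward the
    shorter unit, then lexicographically. The profile is flagged
    informative when the best proportion reaches ``cfg.proportion_repeat``.
    """
    n = len(seq)
    profile = KmerProfile(read_length=n)
    if n < cfg.min_k:
        return profile
    merged: dict[str, int] = {}
    for k in range(cfg.min_k, cfg.max_k + 1):
        if k > n:
            break
        for unit, count in count_nonoverlapping(seq, k).items():
            if count > merged.get(unit, 0):
                merged[unit] = count
    if not merged:
        return profile
    best = min(
        merged.items(),
        key=lambda it: (-(it[1] * len(it[0])), len(it[0]), it[0]),
    )
    profile.counts = merged
    profile.best_unit = best[0]
    profile.best_proportion = best[1] * len(best[0]) / n
    profile.informative = profile.best_proportion >= cfg.proportion_repeat
    return profile


def unit_gc_percent(unit: str) -> float:
    """GC content of a repeat unit as a percentage, one decimal place."""
    if not unit:
        raise ValueError("empty unit")
    gc = sum(1 for ch in unit.upper() if ch in "GC")
    return round(100.0 * gc / len(unit), 1)
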