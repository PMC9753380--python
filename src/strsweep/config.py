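"""Pipeline-wide tunable parameters.

A single :class:`SweepConfig` instance is threaded through every stage so
that thresholds (informative-read proportion, minimum support, MAPQ cutoff,
window geometry) stay consistent between indexing, extraction, discovery,
calling and outlier testing.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SweepConfig:
    """Parameters shared across the STR expansion detection pipeline.

    Attributes
    ----------
    min_k, max_k:
        Range of repeat-unit lengths (bp) scanned with non-overlapping
        k-mer counting. Units of 1 bp arise via homopolymer collapse.
    proportion_repeat:
        Minimum fraction of a read (or window, or clipped segment) that a
        single repeat unit must account for before the sequence is called
        repeat-informative.
    min_support:
        Minimum number of informative reads from a single sample required
        to report a locus.
    min_mapq:
        Mapping quality below which an alignment is considered unreliable.
    window_size, window_slide:
        Geometry of the reference scan that finds large perfect repeat
        tracts ("sinks").
    min_clip_len:
        Soft-clipped segments shorter than this are not scored.
    cluster_pad:
        Added to the 98th fragment-length percentile to form the
        clustering window around a candidate locus.
    found_window:
        Padding (bp) on each side of a true locus within which a reported
        call with the right unit counts as "found".
    alpha:
        Significance level for the BH-adjusted outlier test.
    depth_baseline:
        Coverage the allele-model predictors are normalised to, so that
        calibrated coefficients transfer across sequencing depths.
    """

    min_k: int = 2
    max_k: int = 6
    proportion_repeat: float = 0.8
    min_support: int = 5
    min_mapq: int = 40
    window_size: int = 100
    window_slide: int = 60
    min_clip_len: int = 8
    cluster_pad: int = 100
    found_window: int = 500
    alpha: float = 0.05
    depth_baseline: float = 30.0

    def __post_init__(self) -> None:
        if not (1 <= self.min_k <= self.max_k <= 6):
            raise ValueError("require 1 <= min_k <= max_k <= 6")
        if not (0.0 < self.proportion_repeat <= 1.0):
            raise ValueError("proportion_repeat must be in (0, 1]")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        for name in ("window_size", "window_slide", "min_clip_len",
                     "cluster_pad", "found_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def cluster_slack(self, p98: float) -> float:
        """Clustering window half-width: p98(fragment) + cluster_pad bp."""
        return p98 + self.cluster_pad


DEFAULT_CONFIG = SweepConfig()
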