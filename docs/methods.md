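# Methods

This note documents the models, parameter choices and numerical
conventions behind `strsweep`, and what the simulator does and does not
emulate.

## Repeat-unit detection

STR content is measured with non-overlapping k-mer counting: a sequence
is scanned k bp at a time for every unit length k ∈ [min_k, max_k] =
[2, 6], and each window is replaced by its *rotation-canonical* form —
the lexicographically smallest rotation under A < C < G < T. Canonical
rotation is what keeps the tally intact across phase-shifting
interruptions (a single inserted base changes which rotation of the
unit subsequent windows contain, not the canonical form). Windows that
are homopolymer-periodic (e.g. `AA`, `AAAA`) collapse to the single
base; the collapsed unit is credited in base units (an `AA` window adds
2 copies of `A`) so that `count × len(unit)` always equals the bases
accounted for, and the reported proportion stays exact.

The representative unit of a read maximises the covered proportion,
with the **full read length** as denominator (not rounded down to a
multiple of k). Ties break toward the shorter unit, then
lexicographically, so a perfect `ATAT…` read reports `AT`, not `ATAT`.
A read is informative when the best proportion reaches
`proportion_repeat` (default 0.8). Windows containing `N` or other
ambiguity codes are skipped but still count in the denominator —
conservative with respect to informativeness. Units are reported on the
reference forward strand; no reverse-complement canonicalisation is
applied. Units are also representable as integers (2 bits/base with a
sentinel pair, injective across lengths 1–6) for compact keying.

Known consequence: units with internal symmetry can alias under a phase
shift — one inserted base turns a perfect `AACC` read into an
alternation whose 2-mers all canonicalise to `AC`. The read stays
informative, but its unit label changes. Primitive disease-locus units
(CAG, AAG, CGG, AAGGG, …) are unaffected; the property suite encodes
both facts.

## Reference sink index

Large perfect repeat tracts in the reference attract mismapped
repetitive reads. The index scans each contig in `window_size` = 100 bp
windows sliding `window_slide` = 60 bp, scores each window with the
same representative-unit machinery, and records windows whose best
proportion reaches `proportion_repeat` (the same 0.8 threshold — the
minimum tract length this implies, ≈ 80 bp of perfect repeat within a
window, is a configurable proxy for "large"). Overlapping or abutting
windows with the same canonical unit merge; mixed-unit adjacency stays
separate. Trailing windows are scored at their natural, shorter length
with the same proportional threshold. The scan is deterministic, so the
index is byte-for-byte reproducible.

## Read extraction and placement

Fragment statistics are estimated per sample from the first 100,000
proper pairs with MAPQ ≥ `min_mapq` = 40, template length capped at
2,000 bp; median and 98th percentile use the "lower" order statistic so
both are observed integer lengths. Samples with fewer than 1,000 usable
pairs are rejected (pipeline helpers lower this floor for small
simulated contigs, where the whole contig yields a few thousand pairs).

Candidate reads are those that are unmapped, low-MAPQ, sink-overlapping
or imperfectly aligned (any I/D/S CIGAR operation, or edit-distance tag
NM > 0 when present; CIGAR-only when the tag is absent). Perfect
non-sink alignments are skipped, as are secondary, supplementary and
duplicate records.

Placement rules per template:

* one mate informative, other mate mapped with MAPQ > 40, itself
  non-repetitive (best proportion < threshold and outside sinks) →
  **anchored pair**, positioned one median fragment length from the
  mate in the direction its orientation implies: a forward mate anchors
  at `mate_start + median`, a reverse mate at `mate_end − median`
  (the fragment's outer end minus the median — the coordinate where the
  repeat-laden mate's fragment began), clamped to the contig;
* both mates informative, or the mate unusable → a single **unplaced
  pair** record with no position;
* informative soft-clipped segments of length ≥ `min_clip_len` = 8 bp
  produce clip records at the clip coordinate regardless of the pair
  class. The 8 bp floor suppresses 1–2 bp clip noise.

Each template yields at most one anchored or one unplaced record.
Spanning reads, spanning pairs and overlapping reads are *not* emitted
at extract time; they are gathered in the targeted second pass at call
time, once loci are known.

## Locus discovery

Anchored and clip records are grouped by (unit, contig) and scanned in
genomic order. A cluster seeds at each unclaimed record and iterates:
centre = median member position, window = ±(p98 + 100) bp; members
outside the window are dropped, unclaimed records inside are admitted,
until membership stabilises (cap 100 iterations). When a left-clip
record enters the cluster the centre is moved to the modal left-clip
coordinate, one final admit pass runs there, and iteration stops — the
clip pins the locus. (Freezing membership at the instant the clip
appears instead leaves the far tail of anchored reads unclaimed, and on
large expansions that tail re-seeds a spurious second locus a few
hundred bp away.)

A cluster is accepted when a single sample contributes at least
`min_support` = 5 records and at least one member is anchored. Bounds:
left = modal left-clip coordinate (ties toward the smaller coordinate),
else the lower-median anchored position; right = modal right-clip
coordinate, else left (point locus). Joint discovery pools all samples'
records and uses the largest per-sample p98 for the window; clusters of
different units may overlap spatially and are reported separately (this
is what lets a novel unit, e.g. CANVAS-type AAGGG, be called on top of
an annotated locus of a different unit). Same-unit overlapping output
intervals are merged so reported loci never overlap. Records are sorted
before scanning, so shuffled inputs yield identical loci.

## Allele-size estimation

Evidence per sample × locus:

* **spanning reads** — primary, well-mapped, clip-free alignments
  strictly covering the locus; their mean net CIGAR indel size
  (insertions − deletions) estimates alleles shorter than the read
  length; no spanning reads → no short-allele estimate;
* **anchored pairs** assigned to the locus (same unit, position within
  the clustering window) contribute their non-overlapping repeat-copy
  counts to `sum_str_counts`, as do informative reads aligned inside
  the locus (overlapping reads);
* **unplaced pairs** carry no position; each is assigned to the
  same-unit locus with the greatest anchored support in that sample,
  ties left unassigned (two same-unit expansions in one genome are
  genuinely ambiguous);
* **local depth** — mean aligned depth over locus ± median fragment.

Two ordinary-least-squares regimes map evidence to inserted bp, with
predictors divided by `local_depth / depth_baseline` (baseline 30×) so
coefficients transfer across coverages: the small regime regresses
allele size on normalised `sum_str_counts` over calibration alleles ≤
the median fragment length; the large regime on normalised unplaced
pairs over larger alleles. Calibration uses the built-in simulator
(heterozygous grid, 30 sizes over 0–1,800 bp at 30×); the shipped
default coefficients come from that calibration at read length 150,
fragment Normal(400, 50), and can be regenerated with
`calibration_grid` + `calibrate_allele_model`.

**Regime switch.** The long-allele estimate starts as the small-regime
prediction and switches to the large regime when unplaced pairs exist
and *either* regime places the allele beyond the crossover (the median
fragment length). Conditioning the switch on the small-regime
prediction alone is unreliable: the summed-repeat-count predictor
saturates near the median fragment length, and with count noise at
realistic depth its OLS prediction at saturation sits below the
crossover, stranding large alleles in the saturated regime. Unplaced
pairs only arise once the allele approaches the fragment length, so
their own prediction clearing the crossover is the more robust trigger.

Estimates are floored at 0 and ordered (allele1 ≤ allele2). Zygosity
hint: no spanning reads and ≤ 2 spanning pairs alongside expansion
evidence → HOM_OR_HEMI (an expansion ≫ read length on both haplotypes
leaves nothing to span); a short allele observed alongside expansion
evidence → HET; otherwise UNKNOWN. The "few spanning pairs" cut-off of
2 is a package choice.

`sum_str_counts` counts non-overlapping unit *copies* (not repeat
bases); the regression slope absorbs the factor, so the convention is
calibration-consistent by construction.

## Outlier prioritisation

Per locus, each sample's count is normalised as
`log2((sum_str_counts + 1) / local_depth)`; zero-depth entries are
missing (excluded from the conditioning set, no record emitted — this
avoids −∞ norms). The z-score uses the cohort median and the n−1
standard deviation; p is the one-sided upper-tail standard-normal
probability. Degenerate loci (sd = 0) report z = 0, p = 1 rather than
being dropped, so every usable (sample, locus) pair has exactly one
record. Loci with fewer than 3 usable samples are skipped. BH
adjustment (step-up, monotone, capped at 1, input order preserved) runs
across all loci *within each sample*; significance at `alpha` = 0.05.
A control-conditioning mode computes median/sd from a designated
control subset while still scoring all samples. Post-filters can drop
homopolymer-unit loci and loci overlapping supplied BED intervals
(low-complexity regions, segmental duplications).

## Simulator

The generator builds a contig (default 20 kb — an order of magnitude
above the fragment length, so locus neighbourhoods are fully contained)
whose centre carries a 10-copy perfect seed tract of the chosen unit;
donor haplotypes extend the tract in phase by allele1/allele2 bp.
Flanks are seeded random sequence rejected until free of incidental
tracts (≥ 3 unit copies in any rotation or reverse complement; ≥ 8
copies for 1 bp units, which random sequence cannot avoid at 3).
Fragments are drawn uniformly along each haplotype at half depth each,
lengths Normal(400, 50) truncated to [2 × read length, 3 × mean] —
note the truncation is asymmetric, so the realised mean sits ~3 bp
above the nominal mean. Reads are error-free by default (oracles stay
exact); a uniform substitution rate is available for robustness tests.

Alignment is **rule-based emulation**, not a real aligner, keeping
tests hermetic and byte-reproducible from the truth record: reads
wholly outside the insertion map perfectly (MAPQ 60); reads straddling
an insertion edge are soft-clipped at the insertion point (the side
with ≥ 20 aligned bp anchors the alignment); insertions that fit within
a read with ≥ 20 bp flanks on both sides are emitted as an `I` CIGAR
operation, as real aligners do for small indels — this is what makes
spanning-read indel estimation exercisable; reads wholly inside the
inserted repeat are unmapped (parked at the mate's coordinate when one
exists), or mapped to the largest same-unit sink with MAPQ 0 when a
sink list is supplied. MAPQ is binary (60/0) so behaviour at the
`min_mapq` = 40 threshold is unambiguous. Unmapped-read sequences are
stored reference-forward (emulating the orientation a mate-rescued
placement would give), since units are not reverse-complement
canonicalised.

What the simulator does **not** model: PCR stutter, GC-coverage bias
(the known Fragile-X-type underestimation is therefore invisible here),
sequencing-error-induced unit miscounts at default settings, repeat
interruptions in the donor, mismapping to *partially* matching sinks,
and real-aligner idiosyncrasies (sub-maximal clips, mismatch-tolerant
extension through short insertions). Passing tests demonstrate the
pipeline's logic and its quantitative behaviour under clean mapping
semantics, not performance on real genomes.

## Evaluation metrics

`position_error` scores each call bound separately — 0 if inside the
truth interval, else distance to the nearer truth edge — and returns
the worse side; calls on the wrong contig return a not-found sentinel.
`locus_found` requires the canonical unit to match and the call to
overlap the truth interval padded by `found_window` = 500 bp per side.

## Problem sizes and determinism

Test and reproduction runs use 20 kb contigs at 30× (≈ 2,000 read
pairs per sample), a 30-point allele grid, 50 replicate two-sample
cohorts for position accuracy, and a 50-sample cohort (6 kb contigs)
for outlier detection — sizes chosen so the full suite completes in
minutes on one CPU while every rate is estimated from ≥ 30
observations. All randomness flows from explicit integer seeds;
regenerating from a serialized truth record reproduces the BAM's SAM
text exactly.

## Known limitations

* Allele sizes are systematically noisy near the read length (too long
  to span, too short for a strong anchored signal) — the same "gray
  area" any paired-end method has.
* Bounds without clip evidence collapse to a point at the median
  anchored position; accuracy is then fragment-scale, not base-pair.
* Two same-unit expansions in one sample split unplaced-pair evidence
  ambiguously; sizes are underestimated although both positions are
  still discovered.
* The outlier test assumes approximate normality of normalised counts
  across the cohort; heavy-tailed cohorts inflate the tail rate.
* Composite loci (e.g. (TG)n(TCTG)n(CCTG)n) are represented as separate
  per-unit loci, not as one haplotype structure.
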