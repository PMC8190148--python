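# Methods

This note records the models implemented in `mareta`, the defaults and
numerical choices, what the synthetic generators do and do not emulate,
and the design decisions taken where the procedure was genuinely open.

## Abundance quantification (`mareta.quantify`)

Per-read alignments are reduced to mapped-read counts per (contig,
sample) after an identity filter that is **strictly** greater-than
(default 0.90): a read at exactly 90% identity is dropped. Counts become
absolute abundances via

copies/L = m_DNA · (n_mapped / n_total) · N_A / (616 · L_bp) / V,

with N_A = 6.02×10²³ mol⁻¹ and 616 g/mol per base pair. Assumptions: the
extracted DNA mass is representative of the filtered volume, mapping
fractions are proportional to molar fractions weighted by length, and
ploidy/copy-number effects are ignored. Units: DNA mass is carried in
grams internally; the metadata TSV stores nanograms (the bench unit) and
the loader converts. The 616 g/mol constant is a named, overridable
parameter (`bp_molar_mass_g`).

The formula's length term is applied at **contig** granularity here and
re-applied at MAG granularity (summed member length) downstream, because
per-contig abundance exists before MAGs do. `build_abundance_matrix`
optionally keeps only the `top_n` contigs by total mapped reads (ties by
lexicographic contig id) — the device used at scale to cap the contig set
— and orders rows by that rank and columns by sample date then id, making
output independent of input record order. Identity from SAM records is
`1 − NM/span` with deletions counted in the span.

## MAG clustering (`mareta.mag_cluster`)

Greedy canopy clustering at Pearson **r ≥ 0.95** on raw copies-per-liter
profiles (no transformation by default; `log1p` is available). Seeds are
taken by decreasing total abundance (ties by id), which makes the result
invariant to row order. After the initial gather around the seed profile,
the canopy centroid (member mean) is recomputed and membership
re-gathered until stable (default) or at most `max_iterations` times;
`refine=False` gathers once around the seed only. The seed stays anchored
to its canopy during refinement so every contig is assigned exactly once.
Flat (zero-variance) profiles have undefined correlation; they are
reported as unclustered rather than allowed to seed. Requires ≥ 3
samples — Pearson on fewer points is meaningless.

MAG summaries: length = summed member lengths; profile = member mean (the
clustering centroid; the member sum is also kept); the longest member
contig (ties by lexicographic id) is recorded because BLAST–MAG
annotation adopts its assignment.

## CCP classification (`mareta.ccp`)

Per-genome Pfam profiles are plain counts of domain accessions (version
suffixes stripped). Query–reference similarity is Pearson correlation
over the **union** of accessions present in either profile, zeros for
absences; intersection-only correlation would inflate similarity between
genomes sharing few domains. Raw counts are correlated (no
normalization) — Pearson is scale-invariant, so sequencing depth cancels.
Ties at the best correlation break by larger shared-accession count, then
lexicographic genome id. Queries with fewer than `min_domains = 5` domain
instances are reported `unclassified`: a correlation supported by fewer
points is noise. Agreement between CCP and BLAST annotations is computed
only over MAGs annotated by both methods, at a named rank or at the
binary virus-vs-cellular level. The reference database serializes to a
single versioned JSON document that reloads bit-identically.

## BLAST/LCA taxonomy (`mareta.taxonomy_lca`)

Bit-score filter strictly > 100 (default). LCA is the longest lineage
prefix shared by participating hits; with `top_percent` (default 10),
only hits within that percentage of the best bit score participate —
mirroring common LCA-binning defaults; `top_percent=None` uses all
filtered hits. Lineages with incompatible roots collapse to a synthetic
`root` node (still "assigned"). No minimum-support rule is applied.
Composition normalization rescales counts to exactly `total` (default
1000, no-hit bin excluded) by largest-remainder rounding with
lexicographic tie-breaks, so the output always conserves the total
exactly.

## Tandem-repeat scanning (`mareta.repeat_scan`)

A run of period *k* starting at *i* extends while `s[j] == s[j−k]`, so
partial trailing unit copies count in whole bases (maximal periodic
extension); a run must span at least two full unit copies. Units must be
primitive — (TA)₄ is a unit-2 run, never a unit-4 one — and are named by
the lexicographically smallest rotation of the unit (reports also print
the alphabetical rotation list, so TAG-repeats appear as AGT/GTA/TAG).
Unit lengths 2–10 are scanned; homopolymers are therefore out of scope by
construction. N bases split runs; reads with more than 50% N are skipped
but still counted as scanned.

A read's call uses its single best rotation class (coverage = union of
that class's run intervals; ties by lexicographic canonical unit):
`is_repeat_read` iff coverage strictly exceeds 70% of the read length
(the >70-of-100-bp rule, scaled proportionally for other read lengths).
Reverse-complement classes are **not** merged by default (forward and
complement repeats are biologically distinct probes); `merge_rc=True`
merges them. Per-sample fractions are over all scanned reads. The scanner
is verified against a brute-force oracle that enumerates every offset,
unit length and phase.

## Periodicity classification (`mareta.periodicity`)

The recurrence rule needs a peak definition, which is this package's
addition: a strict local maximum (endpoints one-sided) at least 10% of
the series maximum (`min_height_frac`, exposed and logged). Dates map to
calendar month indices with mid-month rounding rather than 30-day bins.
A peak recurs when another peak lies 12 ± `month_tolerance` (default 1)
months later with height ≥ `recurrence_frac` (default 0.25) of it. With
T = span//12 year-to-year transitions, a series is COMPLETE_CYCLIC when
every transition window [12t, 12(t+1)) contains a recurring peak,
INCOMPLETE_CYCLIC when at least one but not all do, TRANSIENT with
exactly one peak, IRREGULAR otherwise. A year with no peak is a failed
transition, not a skipped one. Raising `recurrence_frac` can only degrade
COMPLETE → INCOMPLETE → IRREGULAR; scaling abundances never changes the
class.

## Digital DNA chip (`mareta.ddc`)

A probe hits a read when the read contains the probe or its reverse
complement, exactly by default; `max_mismatches` allows Hamming
mismatches within probe-length windows. Positivity threshold
`min_hits = 1`. Both knobs are logged — hybridization stringency is
inherently instrument-specific and no equivalence to any physical chip is
claimed. Probes are input artifacts; deriving environment-associated
probe sequences is out of scope. The chip grid is the smallest
near-square layout (cols ≥ rows; 748 probes → 27×28 with 8 blanks);
rendering is a plain-text PPM (P3) plus an ASCII grid, bit-exact for a
fixed chip.

## Synthetic generators (`mareta.simulate`)

All generators use numpy's PCG64 `default_rng` under an explicit seed;
identical arguments give bit-identical outputs.

*Repeat reads* — exactly `round(p·n)` reads carry one planted run of the
stated unit class covering strictly more than the threshold fraction
(random run length, offset and phase); background reads are uniform
random and re-drawn until they contain no qualifying run, so the planted
fraction is exact by construction, not in expectation.

*Community time series* — 25 monthly samples by default, 20 MAGs over 500
contigs. Each MAG has a seasonal template: a sharpened annual sinusoid
(`(0.05 + ((1+sin)/2)³)`, bloom-like), the same with the final year's
peak suppressed to 5%, a single Gaussian pulse (σ = 1.5 months), or two
pulses separated by far-from-12 months. Sinusoid phases are drawn without
replacement, and pulse placements are rejected until every pair of
templates satisfies |r| < 0.90: at a 25-month span an "incomplete" bloom
retains only a single peak and can otherwise coincide with a transient
pulse, which would make two planted MAGs genuinely indistinguishable at
the 0.95 clustering radius. Contig profiles are the MAG template times a
contig-specific lognormal scale times mean-one multiplicative lognormal
noise with CV 0.10 (σ² = ln(1+CV²)) — positive and heavy-tailed, the
standard model for coverage noise. The archetype fixture bank
(`simulate_pattern_series`) uses 31 monthly points so an annual bloom has
phase freedom while keeping both of its repeat peaks inside the span.

*Pfam profiles* — 50 references over a 100-accession vocabulary, each
holding 20–50 accessions with multinomial counts (Dirichlet weights,
150–400 total domains); queries binomially thin a source genome's domain
instances at retention 0.5 and add ~2% uniform contamination.

What the generators do **not** emulate: sequencing error profiles,
GC/mappability bias, taxonomically realistic gene content, shared domains
between related reference genomes, gaps or irregular cruise spacing in
the time series, and real probe/target thermodynamics. Passing tests
therefore demonstrate correctness of the rules and recoverability of
planted structure under the stated noise — not performance on real
coastal metagenomes, where cross-mapping, strain mixtures and uneven
sampling will degrade every stage.

## Problem sizes

Test and acceptance runs use 500 contigs × 25 samples for clustering,
50 references × 200 queries for CCP, 100 series for periodicity, and
1,000 reads for the scanner-vs-oracle comparison — sizes at which every
behaviour of interest is already exercised and planted-structure recovery
is measurable with tight margins, while the whole suite completes in
seconds.
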