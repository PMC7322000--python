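# Methods

This note documents the statistical procedures `retroquant` implements,
the generative model behind its synthetic data, the defaults that matter,
and the numerical conventions — in enough detail to reproduce or audit
any number the package computes.

## Coordinates and formats

All internal coordinates are 0-based half-open. 1-based inclusive
conventions exist only at format boundaries: SAM positions (converted by
pysam) and RepeatMasker `.out` rows (begin−1 → start), so a RepeatMasker
row spanning begin..end maps to an interval of identical length. Repeat
annotations travel as BED6 with the hierarchy packed into the name field
(`subfamily|family|class|role`, role one of `five_prime_ltr`, `internal`,
`three_prime_ltr`, `solo`, `unassigned`); an optional seventh column
carries an explicit instance id, otherwise ids are `<subfamily>.<n>` in
file order. Strand is stored but ignored by all counting (repeat-level
quantification is unstranded here; this is a documented limitation, since
a stranded library could in principle separate sense and antisense repeat
transcription). Fragments read from SAM keep mapped primary alignments
only; mapping quality 0 sets the multimapper flag (with a bowtie2-style
aligner every read reports a single location, so each fragment has exactly
one position and the flag merely records ambiguity).

## ChIP enrichment

Duplicates are removed per sample by keeping the first fragment in
(contig, start, end) sort order among those sharing (contig, start,
strand) — single-end rmdup semantics; the operation is idempotent.

Fragments are assigned to repeat units (subfamily by default; family or
class selectable) by the **midpoint rule**: a fragment belongs to the unit
containing `start + (end − start) // 2`, at most one unit per fragment,
which resolves LTR/internal boundary fragments deterministically. Two
alternatives are kept for sensitivity analysis: `any_overlap` (the unit
with maximal overlap, ties to the smaller start then lexicographic
instance id) and `fractional` (overlap-proportional weights summing to
≤ 1). In every mode assigned + unassigned equals the fragment total.
Fragments are counted as read-length intervals; no fragment-size extension
is applied (an option worth adding for single-end data with long
sonication fragments).

Enrichment of unit *u* is

    E(u) = mean_i cpm_i(u) / mean_j cpm_j(u),

with cpm = count × 10⁶ / library_size, i over treatment (ChIP) replicates
and j over the matched control group (input, or IgG when no input exists
for the target; target-matched controls take precedence over shared
untargeted ones). Averaging on the cpm scale, not raw counts, keeps a
deeply sequenced replicate from dominating the mean. Units whose control
mean is zero are flagged `control_zero` and excluded from classification
instead of producing infinities. A unit is called occupied when
E > τ with τ = 1.5 by default — the threshold is a reporting convention,
not a significance statement, and is configurable.

Whether published repeat-level ChIP ratios are computed on per-fragment
counts or per-bp coverage is often ambiguous; counts with cpm
normalization is implemented here, and a coverage-ratio mode would be the
natural extension.

**ICR occupancy** applies the same ratio per imprinting control region
(midpoint counting inside the ICR interval) for each of ≥ 2 targets, then
cross-classifies ICRs as enriched in both, either, or neither target at
τ; ICRs with a zero control mean in any target are excluded from the
summary denominators.

**LTR metaprofile.** For each complete element copy (detected as three
contiguous same-strand intervals whose roles read 5′LTR–internal–3′LTR
along the element's own orientation), per-bp coverage over each segment is
rescaled to a fixed number of bins by exact mean pooling (fractional bin
edges integrate the piecewise-constant coverage), minus-strand copies are
reversed so bin 0 is always the element's 5′ end, and bins are averaged
across copies. The scalar contrast mean(5′LTR bins)/mean(3′LTR bins)
summarizes promoter-biased occupancy.

## Repeat RNA quantification

Reads overlapping (≥ 1 bp) an rRNA interval are removed first, then reads
overlapping an mRNA interval; a read overlapping both counts as rRNA, and
input = rRNA + mRNA + retained holds exactly. The retained count is the
library size for all downstream normalization.

    FPKM(u) = count(u) × 10⁹ / (length(u) × library_size)

where length(u) is the summed bp of the unit's copies. The background
level B is the FPKM of all DNA-transposon repeats pooled as one unit
(total background count over total background bp) — DNA transposons are
transpositionally dead in the mouse genome, so signal there is
nonspecific. Then

    adjusted_FPKM = max(FPKM − B, 0),
    adjusted_cpm  = adjusted_FPKM × length(u) / 1000,

i.e. the per-kb step is inverted exactly, so background removal is the
only net transformation; the pooled background unit itself has adjusted
values identically zero, and negative residuals are floored (the
subtraction formula is a design choice here — "background-adjusted" admits
other readings — with a `mean_of_units` mode as the alternative).

**Fold changes.** Size factors come from the classical median-of-ratios:
per sample, the median over units with an all-positive geometric mean of
count / geometric-mean-count. Because cpm already divides by depth, the
residual composition factor sf × gm(lib)/lib (rescaled to geometric mean
1) is divided out of adjusted cpm, and

    log2FC(u) = log2((mean_a + p) / (mean_b + p)),  p = 0.5 cpm,

with replicate means taken on the normalized adjusted cpm. No dispersion
shrinkage, no Wald tests, no p-values: the reproduced quantity is the
fold change itself. Two caveats follow directly from the estimator and
are worth knowing: (i) a global expression shift affecting most units is
unidentifiable (the size factors absorb it) — the method assumes a
majority-stable unit set, and the normalization degrades when only a
handful of units anchor the median; (ii) **background-class units are
excluded from fold-change calls**: after subtraction their adjusted
expression is the floored residual around zero, where ratios measure
noise and the pseudocount, not biology (under the null their apparent
|log2FC| is an order of magnitude larger than that of expressed units).

A unit is called **reactivated** when log2FC > 1 and its
treatment-condition mean adjusted cpm exceeds 1 (both configurable).

## Interaction screen

Unique-peptide counts in a reference (methylated) and comparison
(demethylated) condition give, per protein,

    R = (n_ref + c) / (n_cmp + c),  c = 1,

finite and positive for any counts. A protein is *shown* when
max(n_ref, n_cmp) ≥ 3 and a *hit* when max(n_ref, n_cmp) > 6 and R > 2
(the depletion filter is applied to pseudocounted counts for consistency
with the ratio; a raw-ratio variant and a reference-condition-only
detection variant are switches). Ranking is by R descending, ties by
n_ref descending then protein id, so output order is byte-stable.
`top_dependent` reports the rank-1 shown protein and its separation
R₁/R₂, flagging a clear top at separation ≥ 2. Swapping the conditions
negates every log2 R exactly.

## Synthetic data

The generator plants every parameter the pipeline estimates and is a pure
function of (config, seed); the same seed reproduces every byte.

**Genome.** `n_contigs × contig_length` of uniform random nucleotides
(sequence content is inert — the pipeline consumes alignments — and can be
skipped for speed). Repeat copies are placed uniformly at random without
overlap (largest elements first, bounded retries, total repeat length
capped at 80% of the genome); LTR-structured families emit
5′LTR/internal/3′LTR intervals per copy with equal LTR lengths; ICRs are
placed in repeat-free gaps. No mappability structure is emulated: real
repeat alignments suffer multimapping ambiguity that a uniform random
genome cannot show, so tests here validate the counting statistics, not
alignment fidelity.

**ChIP fragments.** A target defines a piecewise-constant intensity e(x):
1 everywhere, multiplied by the subfamily's enrichment over its intervals,
by the promoter boost over 5′LTR intervals only, and by per-ICR factors.
Exactly `depth` fragment midpoints are drawn from the normalized
intensity, fragments are `fragment_length` bp with random strand, and
controls use e(x) = 1. Because each sample is normalized to its own
depth, the expected measured ratio is not e but e × L / Z with
Z = ∫ e(x) dx — enriched regions soak up a share of the fixed depth. The
generator records both the planted e and this composition-corrected
expectation in the ground truth. The simulator emits no PCR duplicates,
so evaluation pipelines count its output directly; on a megabase genome
at these depths, identical start positions are expected chance collisions
and rmdup-style removal would selectively thin enriched regions
(duplicate removal is exercised on inputs that do contain artifactual
duplicates).

**RNA counts.** Counts-level simulation (family counting, not alignment,
is the unit under test). Unit abundance weights on a nominal per-million
scale are background (10 cpm per kb of unit length, the nonspecific floor
that DNA transposons measure in pure form) plus planted signal ×
2^(condition effect); the non-repeat transcriptome weight is fixed at its
baseline value, so planted effects shift library composition the way
genuine reactivation does. Counts are negative binomial with dispersion
0.1 **per repeat copy** (Var = μ + 0.1 μ²), summed to the unit — placing
the biological noise at the locus level, where it belongs; a subfamily of
m copies then has effective unit-level dispersion 0.1/m, which is what
makes triplicate fold-change estimates usable at these unit sizes. Each
replicate's library size is its realized total.

**Peptide tables.** Background proteins share a latent abundance between
conditions: counts are C + U with a common Poisson component of mean
ρ × λ (ρ = 0.9, λ = 5), preserving Poisson(λ) marginals while mimicking
the strong run-to-run correlation of peptide counts for
methylation-independent interactors — the feature that keeps the null
false-hit rate low. Planted hits draw independent Poisson counts at their
distinct per-condition means (default one hit at (20, 2)).

## Study configurations

`retroquant.presets` fixes one named configuration per question — null
calibration, enrichment recovery, metaprofile, ICR occupancy, RNA
null/recovery/reactivation, screen — as constants of the package. Scaled-
down dimensions (2 Mb single-contig genomes, 10⁵ ChIP fragments per
sample, 10⁵–10⁶ RNA fragments, 50-protein screens) keep any run to
seconds while leaving relative sampling error far below the planted
effects. Two sizing choices are deliberate: the enrichment-recovery
landscape keeps the enriched footprint near 1% of the genome so the
composition bias e × L / Z stays inside the recovery tolerance (at large
enriched fractions the bias is a property of cpm normalization itself,
not an estimator error); and the log2FC-recovery landscape carries twelve
additional unchanged expressed subfamilies so the median-of-ratios
reference set has the stable majority it assumes. The reactivation
configuration uses one library per condition, matching the design of a
targeted-perturbation experiment; the grid-recovery configuration uses
3 vs 3 replicates.

## Numerical conventions and degenerate inputs

Fragment midpoints use the floor convention start + (end − start) // 2.
bedGraph output is run-length merged with zero runs omitted and values
written with `repr`, so a write/read round trip is exact. Zero library
sizes, empty annotations, all-zero conditions, missing background classes
and malformed files raise typed errors (`ParseError`, `ValidationError`,
`UsageError`) naming the offending line or key; a depth-0 simulation
yields an all-zero table that downstream stages reject informatively.
Ranking and output files are byte-stable under a fixed seed: ties are
fully specified, and run directories include a SHA-256 checksum manifest.

## Known limitations

Multimapping reads are flagged but not redistributed (no EM
reassignment); counting is unstranded; ChIP fragments are not extended to
an estimated fragment size; ICR occupancy is interval enrichment, not
peak calling; fold changes carry no significance estimates; and the
synthetic genome's uniform sequence cannot exercise mappability or
alignment artifacts, so agreement on synthetic data demonstrates the
statistics, not robustness to real-alignment pathologies.
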