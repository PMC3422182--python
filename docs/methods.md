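# Methods

## Cytosine contexts and the locus model

A cytosine's methylation context is decided by the two bases immediately
3′ of it on the same strand: CG if the next base is G, CHG if the next
base is H (A/T/C) and the one after is G, CHH if both are H. The
classifier inventories only the supplied (top) strand; the bottom strand
is analyzed by classifying the reverse complement, which is how
single-strand bisulfite clone data are actually read. A cytosine within
two bases of the end of a sub-fragment has no decidable context and is
labeled UNDEF and excluded from all summaries — unless the caller
supplies the true 3′ flanking sequence (amplicons are sub-fragments of a
longer locus, so flank injection restores the real context; the
amplicon-merging tests use exactly this). Non-ACGT characters are
rejected by default; a lenient mode maps affected sites to UNDEF instead.

Coordinates are 1-based inclusive throughout the library. A coordinate
pair printed with start > end denotes a minus-strand fragment and is
normalized to (min, max, strand = −); length is |start − end| + 1.
Exported tracks use each format's native convention (BED and bedGraph
0-based half-open), converted only at the writer boundary.

Regions (upstream / cds / downstream, extensible) must tile the locus
exactly — no gaps, no overlaps — and every site carries the name of the
unique region containing it. Which strand of the studied fragment is
analyzed is a user choice: the fixture assumes the coding strand, and
nothing downstream depends on that assumption.

## Synthetic data generator

The generator defines the study conditions every downstream stage is
tested under.

**Locus construction.** Each region is assembled from self-contained
context tokens — `CG`, `CHG` and `CHH` with H drawn from {A, T} so no
token contains a second cytosine — shuffled into C-free filler drawn
from {A, G, T}. Because every C and its deciding bases live inside one
token, per-region context counts are met exactly, without rejection
sampling; a (lo, hi) target range is sampled once and then met exactly.
The default profile mirrors the studied 1012-bp monomer: 430 bp upstream
(3 CG / 6 CHG / 51 CHH), 369 bp coding (11/20/52), 213 bp downstream
(2/1/28). The construction is verified against the context classifier
after assembly. A side effect worth knowing: with H ∈ {A, T} the
generated sequences cannot contain `ATGCAT` or other C-bearing motifs in
the filler, so restriction-screen loci are constructed explicitly rather
than drawn from this generator.

**Methylation landscape.** Per-site probability
p_i = rate(region_i, context_i) × f(context_i). Default wild-type rates:
CG and CHG 1.0 in every region, CHH 0.03 / 0.12 / 0.06 in
upstream / coding / downstream. A genotype is a per-context
multiplicative factor; the RdDM mutant default f_CHH = 0.25 corresponds
to a 75 % CHH reduction, inside the 65–80 % band the comparison is
checked against. Wild type is the identity.

**Clone reads.** Each clone methylates every site independently with
p_i, then applies bisulfite chemistry per cytosine independently: an
unmethylated C reads as T with probability `conversion_rate` (default
0.995 — a realistic efficiency chosen once and configurable, since no
realized efficiency is available to copy), a methylated C reads as T
with probability `overconversion_rate` (default 0), and every base can
be substituted at `seq_error_rate` (default 0.001, Sanger-scale). There
is no neighbor-dependent conversion model and no indel or chimera
simulation, so clones always have the locus length and ungapped
alignment is exact downstream. Non-conversion deliberately surfaces as
false methylated calls — the artifact the conversion control exists to
bound — so the QC path is genuinely exercised. The simulator returns the
per-clone truth matrix so zero-noise recovery can be asserted exactly.

**Conversion control.** A separate locus with all p_i = 0 and C-dense
regions (the control's whole purpose is informative positions), plus
clones drawn with the same error model.

**Small-RNA libraries.** Reads are exact substrings of the supplied
loci, drawn multinomially: locus by expression × genotype factor, length
from a distribution over {21, 22, 23, 24}, start uniform, strand fair.
Abundances are multinomial over a fixed read total rather than
negative-binomial per signature — simpler, and sufficient for testing
the normalization identities; it does mean a genotype factor applied to
*all* loci cancels out, so depletion experiments include an unaffected
background locus. Multi-mapping is controlled by building the matching
background with a configurable number of embedded copies per locus.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: PCR duplicates and amplification bias,
chromatogram/base-quality structure, indels and chimeric clones,
neighbor-correlated conversion failures, genome-scale mapping ambiguity
beyond the engineered copy numbers, and sequencing-depth overdispersion.
Parameter-recovery results here demonstrate the pipeline's correctness
under its stated model, not the wet-lab error budget.

## Clone alignment, calling and QC

Default alignment is anchored and ungapped (clones are primer-delimited
amplicons); a banded gapped mode via Biopython's PairwiseAligner with a
C/T-tolerant substitution matrix exists for robustness, and columns
opposite a gap yield no call. Identity is computed over non-C reference
positions only — C positions carry the signal and must not count as
errors in either direction — with a default rejection threshold of 0.9.
Calls: ref-C read as C → methylated, T → unmethylated, A/G/gap →
ambiguous; sites outside the pairing are uncovered (no call), preserving
the conservation identity methylated + unmethylated + ambiguous +
uncovered = sites × clones.

Conversion efficiency is estimated from the control as
unmethylated / (methylated + unmethylated), overall and per clone; the
estimator is invariant to call order and duplication. QC drops clones
whose measured conversion falls below `min_conversion` (default 0.95 —
conventional bisulfite practice, configurable, since no threshold is
available to copy). Because the control is a separate amplicon, a sample
clone has no individually measured conversion; clones absent from the
per-clone table are retained. Surviving counts below `min_clones`
(default 15, the study's design depth) warn but do not fail; zero
survivors is fatal.

Amplicon matrices are merged to locus coordinates by offset shift, with
a context-consistency check at every site. In overlap zones each
amplicon's clones contribute independent calls — pooling, not averaging —
so the unit of observation stays the clone-site call and per-site depth
may vary along the locus.

## Reporting

Per-site level = 100 · m / (m + u); ambiguous calls never enter
numerator or denominator (they are sequencing artifacts, not epigenetic
states). Detection: a site is detected when at least
`detection_threshold_clones` (default 1, "at least some methylation")
clones call it methylated; detected fractions are reported as
nearest-integer percents in the `m/n (p %)` replica and at full precision
in the machine-readable tables. Detection counts are monotone
non-increasing in the threshold, and all cell values are reproducible by
a naive double loop over (site, clone) — both are tested. Overall level
pools all informative calls in the region × context cell. Empty cells
(no sites) and zero-wild-type comparison cells are emitted as explicit
NA, never 0 — a 0-site cell and a 0-level cell are different facts, and
the studied table itself contains a 0/1 cell that must stay
distinguishable. The genotype comparison reports
100 · (1 − level_mut / level_wt) per cell, per genotype, leaving any
cross-mutant aggregation to the user. Detection depth matters: at 200
clones single-clone detection saturates, while subsampling the same
matrix to the study's 15-clone depth reproduces binomial detection
fractions (~43 % at a 3 % CHH rate). No per-site hypothesis testing is
performed — the outputs are descriptive tallies; a per-cell
χ²/Fisher genotype test could be layered on but is deliberately out of
the default path.

## In-silico MSAP

Enzymes are palindromic, so a top-strand scan (overlap-aware) finds all
sites on both strands. Cut offsets are the standard ones — EcoT22I after
position 5 of `ATGCAT`, MseI after position 1 of `TTAA` — and only
top-strand cut coordinates determine fragment boundaries: band lengths,
not sticky ends, are the observable. The default blocking rule is "any
strand-tagged methylated C within the 6-bp footprint blocks the cut";
since the exact position sensitivity of EcoT22I is not specified
anywhere usable, an explicit-position rule is available as
configuration. MseI's site contains no C, so it is never blocked — a
structural consequence of the rule, not a special case, and tested as
such. Fragment sets tile the sequence and conserve total length under
any blocking pattern; added methylation can only convert cut → blocked,
making fragment counts monotone.

Amplification is modeled as the deterministic filter the chemistry
implements: keep fragments with exactly one EcoT22I and one MseI end
(the labeled primer is EcoT22I-side, so E–E, M–M and terminus fragments
are invisible), whose genomic bases immediately interior to each cut
remnant match that primer's selective 3′ bases (read forward at a left
end, reverse-complemented at a right end), within a gel-visible size
window (default 50–500 bp). Selective bases are parsed from full primer
sequences given a configured adapter+remnant core length; with a 16-nt
core the published primers yield CC (T21), TGT (M56) and TA (M1) — these
are configuration fixtures, not hard-coded behavior. Adapter ligation,
touch-down cycling, radiolabeling and band intensity are not modeled.
Profile differencing reports fragments present in exactly one sample,
each annotated with the (enzyme, site) whose cut mask differs within or
adjacent to the fragment.

## Small-RNA processing

Trimming takes the insert before the left-most adapter occurrence with
≥ `min_overlap` matching bases (default 5) and ≤ `max_mismatch`
mismatches (default 0); reads without a hit are dropped by default
(configurable to keep), and inserts below 18 nt are discarded.
Signatures collapse identical sequences with summed abundances in
lexicographic order, so collapsing commutes with trimming. Matching is
exact, both strands, every occurrence counted; a reverse-complement
palindromic read is counted once at its duplex position. Unique = exactly
one hit in the entire supplied reference set (not per locus);
duplicated = more. Structural-RNA exclusion removes signatures matching
the tRNA/rRNA/snRNA/snoRNA set before normalization, with read-level
accounting that reconciles (excluded + matched + unmatched = total).

TPM = raw × 10⁶ / denominator, the denominator being the retained
genome-matched total (matching exclusion-then-match accounting); a
raw-total denominator is exposed as an option since the published
description does not pin this down. The "normalized to 5 TPM" phrasing
in the source figure legend is ambiguous and is interpreted as standard
per-million scaling with an optional display floor (default off) — an
interpretation, not a fact. HNA = TPM / hits assigned at every position,
so Σ positional HNA = Σ matched TPM exactly. A position belongs to a
locus iff its start offset lies in the locus interval — deterministic,
and boundary-overhanging reads belong to the locus of their start. The
per-locus summary is (HNA sum, 24-nt TPM total, unique-24-nt count); the
per-position length track (21–24 nt) totals must and do reconcile with
the locus aggregates. The repeat-annotation k-mer track counts exact
both-strand occurrences of each k-mer (default k = 20) in a background
set.

## Problem sizes and numerical choices

Parameter recovery is demonstrated at 200 clones — at that depth the
binomial standard error on a 12 % rate over ~10 000 informative calls is
~0.3 points, comfortably inside the ±1.5-point recovery check, with the
known +0.4-point non-conversion bias at 0.995 conversion. Oracle
equivalence runs on 100–300 random instances per operation; sRNA
recovery on 10 000-read libraries. Percent rounding is nearest-integer
only in the formatted replica; machine outputs keep full precision. All
generators take explicit seeds and are byte-reproducible; the CLI writes
a run record (resolved config + version) next to every output set.

## Known limitations

No WGBS/short-read mapping, no chromatogram handling, no PCR-duplicate
detection; restriction-screen modeling stops at band presence/absence
(no intensities, no re-amplification); sRNA matching is exact-only with
no mismatch tolerance and no secondary-structure analysis; no
genome-scale context scanning or annotation retrieval. The deposited
sequencing libraries' absolute read counts are external data and are
outside what a synthetic rebuild can or should reproduce.
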