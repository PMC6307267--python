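# Methods

## Scope and data model

`bekit` couples two engines that share a registry of nuclease profiles
and base-editor presets. The designer enumerates protospacer candidates
and scans genomes for off-target sites; the analyzer quantifies editing
outcomes in amplicon deep-sequencing reads. Both work purely offline on
desk-scale inputs; everything is deterministic given its inputs and, for
the simulator, its seed.

A nuclease profile is a degenerate PAM pattern (IUPAC codes), the side
of the protospacer the PAM abuts (3' for the Cas9 family, 5' for Cpf1),
and spacer-length bounds 15–25 nt with per-enzyme defaults (20 nt;
22 for CjCas9, 23 for the Cpf1s). The registry carries twelve profiles:
the ten Cas9-family enzymes named above plus AsCpf1 and LbCpf1 (TTTV),
which round out the set of enzymes the designer supports. xCas9 3.7 is
registered twice (NG and NGR) so each PAM keeps unambiguous semantics.

An editor preset is the deaminated base (C for CBEs, A for ABEs), the
product set counted as intended (C→{A,G,T}, i.e. C→D, for CBEs; A→{G}
for ABEs), and the editing window in 1-based nucleotides upstream of the
PAM: BE3 13–17, Target-AID 15–19. ABE's window is not standardised in
the literature the presets draw on, so it defaults to BE3's 13–17 and
should be overridden explicitly when a different deaminase geometry is
known. Distance *d* upstream of the PAM maps to 0-based spacer offset
`spacer_length − d` for a 3'-PAM enzyme; for a 5'-PAM enzyme the window
counts from the PAM-proximal end (offset `d − 1`), a convention we fix
because no published one exists for Cpf1 base editors.

## Guide enumeration and off-target scan

The designer scans both strands; wherever the PAM pattern matches
degenerately and a full-length spacer fits, a candidate is emitted with
its spacer, PAM, strand, 0-based half-open protospacer interval on the
input forward strand, 1-based position of the spacer 5' end, GC%, and
the list of editable (substrate-in-window) bases. Candidates with no
editable base are kept but flagged, so the caller decides whether a
guide that cannot edit is still interesting; degenerate query bases are
tolerated in PAM matching (degeneracy sets must intersect) but spacers
containing non-ACGT codes are skipped with a warning. Overlapping
matches of short PAMs (NG) are all reported.

The off-target scan is a vectorised sliding comparison over every offset
of every FASTA record on both strands: the PAM must match its pattern
with zero tolerance and the spacer Hamming distance must not exceed the
bound (default 2). This mirrors the semantics of mismatch-bounded
genome scanners in common use: mismatches count over the spacer only.
Sites overlapping any non-ACGT base are excluded, since a mismatch
against N is undefined; bulges are out of scope. No index structure is
built — at the 100 kb scale the scan verifies against, a linear pass is
instantaneous, and correctness is established by an exhaustive
positionwise oracle in the tests.

## Read preparation

FASTQ input is Phred+33, plain or gzipped; Phred+64 is not supported.
Paired-end merging reverse-complements R2 and tries every overlap length
from `min_overlap` (default 6) upward, choosing the overlap with the
smallest mismatch fraction (ties → longest). The pair is accepted when
that fraction is ≤ `max_mismatch_frac` (default 8%); the defaults follow
the documented behaviour of overlap-consensus mergers. Disagreeing
overlap positions take the higher-quality base (tie → R1) and the max of
the two qualities. Overlaps disagreeing at more than 50% of positions
are treated as chance alignment rather than a real overlap — two
unrelated DNA segments disagree at about 75% of positions — which is
what lets the rejection report distinguish `no_overlap` (no plausible
overlap at all) from `mismatch` (a real but too-noisy overlap).
Unmergeable pairs are dropped and counted, never passed through.

## Amplicon analysis

**Indicator filter.** The first and last 15 nt of the reference are the
indicator sequences (the reference must therefore be ≥ 30 nt). A read
passes if both indicators occur — each with at most one mismatch, left
before right — in either the read or its reverse complement; the
orientation with the lower total mismatch wins, ties going forward.
Passing reads are trimmed from the left indicator's start to the right
indicator's end. Exact string search is used as a fast path; otherwise
every offset is scanned.

**Tally.** Trimmed reads are counted as unique sequences, sorted by
descending count with lexicographic tie-breaks, and sequences below
`min_frequency` (an absolute count, default 1 so nothing silently
disappears) are discarded.

**Alignment.** Each unique sequence is aligned to the reference by a
global Needleman–Wunsch/Gotoh aligner with affine gaps using the classic
DNA scoring of the EMBOSS needle tool: match +5, mismatch −4, gap open
10, gap extend 0.5, where a gap of length k costs `open + k·extend`.
Scores are computed in scaled integer arithmetic (×2, so the half-point
extension is exact) and the traceback is deterministic, preferring
diagonal over gap-in-query over gap-in-reference at every tie. The
tests verify the optimal score against an independent full-DP
implementation (Biopython's `PairwiseAligner`) over hundreds of random
pairs, and re-score the emitted rows independently of the DP.

**Classification.** Variant calls are scoped to the editing window
extended by `flank_left`/`flank_right` reference positions. If any gap
column falls inside that span, the read is an insertion when the
reference row carries the majority of in-scope hyphens and a deletion
otherwise (the equal-count tie goes to deletion — any fixed choice
preserves count conservation, and we document this one). With no
in-scope gaps, one or more in-scope mismatch columns make the read a
substitution; otherwise it is wild type, even if it carries variation
elsewhere in the amplicon — the flanks exist precisely so the user
chooses how far from the protospacer variation still counts. A
substitution read is *intended* when at least one window-proper column
converts the editor's substrate base to a product base; on a
minus-strand target both bases are complemented into reference-forward
space before comparison. An insertion between reference positions p−1
and p is attributed to position p when deciding scope membership.

**Summary.** The nine-field record: total reads, reads with both
indicators, reads above the minimum frequency, and the four class
counts, plus the intended count and
`intended_rate = intended / above_min_frequency`. The four classes
always sum to the third field; a run with zero analyzable reads is an
error rather than a zero-rate result. Headline per-product rates (e.g.
a separate C→T rate) are reported alongside.

**Substitution table.** For the positions spanning window ± flanks, the
percentage of each nucleotide among substitution-class reads covering
the position gap-free (count-weighted), and at substrate positions the
conversion rate toward each product (all three C→T/C→G/C→A for a CBE).
A whole-population variant (`population="all"`) is available for
heat-map-style views. Uncovered positions fall back to 100% reference
base and are distinguishable by zero coverage. Amino-acid context is
provided by translating the displayed region in all three frames,
dropping trailing partial codons.

**Control overlay.** A control run is analyzed identically; its
conversion rates are attached to the treated profile as negative-signed
display values, and positions where the control rate is non-zero and
reaches the treated rate are flagged as background. No counts are
subtracted — the overlay is diagnostic, not arithmetic.

## Simulator

The simulator is the package's ground-truth source. `make_toy_genome`
writes uniform-random ACGT records and plants sites by mutating exactly
the requested number of spacer positions (each to a different base, so
the Hamming distance is exact) next to a concrete realisation of the PAM
pattern, at deterministic non-overlapping coordinates, returning a truth
table of coordinates and mismatch counts. `simulate_edited_reads` draws
reads from the reference with independent per-position substitution
edits (intended and bystander, each a (position, probability, base)
triple), an optional indel at the nominal cut site (3 bp PAM-proximal of
the PAM, insertion or deletion with equal probability, geometric size of
mean 3), and uniform per-base sequencing errors; qualities are constant
Phred 30 by default so golden outputs stay stable. Each read carries a
truth label including the class the analyzer should assign, computed
with the same window ± flanks scoping the analyzer uses. All randomness
flows through `numpy.random.default_rng` (PCG64) under an explicit seed.

What the simulator does *not* model: quality-dependent miscall spectra,
PCR chimeras and jackpots, adapter read-through, coverage variation, or
indels away from the cut site. Passing tests therefore demonstrate the
pipeline's arithmetic and classification logic under the stated
generative model, not robustness to every artefact of real sequencing
libraries.

## Problem sizes and numerical choices

The verification suite runs at deliberate desk scale: off-target oracle
checks on 100 kb genomes, alignment oracle checks on 500 random pairs of
length ≤ 30, rate-recovery on 2,000 simulated reads (binomial three-
standard-error band, ±0.031 at p = 0.30). The aligner's integer scaling
makes score comparisons exact, so tie-breaks never depend on float
rounding; tallies break ties lexicographically; the indicator search
prefers the forward orientation and the leftmost occurrences. Reruns on
identical inputs produce byte-identical outputs (manifests exclude only
the timestamp).

## Known limitations

Off-target scanning is mismatch-only (no DNA/RNA bulges, no scoring) and
linear-time, not indexed — appropriate for the bacterial-genome scale it
is tested at, not for mammalian genomes. The analyzer assumes the
amplicon is short enough for merged reads to span both indicators.
`min_frequency` semantics are an absolute read count. The CBE intended
definition counts any C→D conversion; users wanting strictly C→T should
read the per-product rates.
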