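"""Merge overlapping paired-end reads by overlap consensus.

Shows an accepted merge (with a quality-resolved disagreement) and the
two rejection modes.
"""

from Bio.Seq import reverse_complement

from bekit import SequenceRead, merge_pair

FRAGMENT = "ACGTACGTTTGACCAGGATTACAGGAGTCCTGCATGGCAT"

r1 = SequenceRead("pair", FRAGMENT[:28], tuple([10] * 28))
r2 = SequenceRead("pair", reverse_complement(FRAGMENT[-28:]), tuple([40] * 28))
merged = merge_pair(r1, r2)
print(f"fragment : {FRAGMENT} ({len(FRAGMENT)} nt)")
print(f"merged   : {merged.bases} ({len(merged.bases)} nt)")
print(f"overlap  : {len(r1.bases) + len(r2.bases) - len(merged.bases)} nt, "
      f"round-trips the fragment: {merged.bases == FRAGMENT}")

no_overlap = merge_pair(
    SequenceRead("x", "A" * 12, (30,) * 12), SequenceRead("x", "A" * 12, (30,) * 12)
)
print(f"\ndisjoint pair        -> rejected: {no_overlap.reason}")

noisy = list(r1.bases)
for i in (18, 20, 22, 24, 26):
    noisy[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[noisy[i]]
too_noisy = merge_pair(SequenceRead("y", "".join(noisy), r1.quals), r2)
print(f"noisy overlap (>8%)  -> rejected: {too_noisy.reason}")
print(
    "\nThe best overlap is the one minimising the mismatch fraction (ties\n"
    "go to the longest); pairs whose best overlap exceeds the 8% mismatch\n"
    "ceiling are dropped rather than merged."
)
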