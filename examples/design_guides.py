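"""Enumerate base-editor guide candidates in a short locus.

Prints one row per protospacer found on either strand, with the window
cytosines a CBE could edit, the guide's 1-based position, and its GC%.
"""

from bekit import enumerate_targets, get_editor, get_profile, parse_sequence_input

LOCUS = (
    ">demo_locus\n"
    "GATTACAGGACCTGAACGTACGTTTGACCCAGCATTACAGGAGTCCTGCATGGCATACAATGG\n"
)

region = parse_sequence_input(LOCUS)
candidates = enumerate_targets(region, get_profile("SpCas9"), get_editor("BE3"))

print(f"{len(candidates)} SpCas9/BE3 candidates in {len(region.sequence)} nt:")
for c in candidates:
    editable = ", ".join(f"C@{o}" for o, _ in c.editable) or "none"
    print(
        f"  {c.spacer} {c.pam} strand {c.strand} pos {c.relative_position:3d} "
        f"GC {c.gc_percent:5.1f}%  editable: {editable}"
    )
print(
    "\nEach row is one protospacer whose PAM matches NGG; 'editable' lists\n"
    "spacer offsets (0-based) of cytosines lying 13-17 nt upstream of the\n"
    "PAM, i.e. the bases BE3 is expected to convert."
)
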