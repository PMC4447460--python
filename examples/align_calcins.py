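"""Percent identity between a transcript calcin and reference calcins."""
from venomkit import global_align, load_calcin_references, load_table2, percent_identity

comp749 = next(r.mature for r in load_table2() if r.name == "comp749_c0_seq1")
for ref in load_calcin_references():
    pid = percent_identity(comp749, ref.seq)
    print(f"vs {ref.description.split(';')[0]}: {pid:.1f}% identity")
print()
print(global_align(comp749, load_calcin_references()[0].seq))

# The venom-gland calcin is ~70% identical to imperatoxin-A and ~88% to
# maurocalcin: a ryanodine-receptor-targeting inhibitor-cystine-knot peptide.
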