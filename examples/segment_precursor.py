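"""Segment a venom peptide precursor into signal / mature / propeptide.

Builds the curated NDBP precursor UyCT3 (transcript comp17) from the
packaged table and shows how the pipeline cuts it.
"""
from venomkit import load_table2, segment

row = next(r for r in load_table2() if r.name == "comp17_c0_seq1-4")
seg = segment(row.precursor)

print("precursor :", seg.precursor)
print("signal    :", seg.signal_seq)
print("mature    :", seg.mature_seq)
print("amidated  :", seg.amidated, f"(motif {seg.motif})")
print("pro_c     :", seg.pro_c_seq)

# The 23-residue signal peptide targets secretion; the 13-residue mature
# peptide is the secreted antimicrobial; the GKR motif's glycine donates the
# C-terminal amide and the acidic C-propeptide is removed during maturation.
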