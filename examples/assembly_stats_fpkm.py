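"""Assembly statistics (N50) and FPKM expression values."""
from venomkit import GeneratorConfig, assembly_stats, fpkm, generate_dataset

ds = generate_dataset(GeneratorConfig(seed=7, n_decoys=20))
st = assembly_stats(ds.transcripts)
print(f"{st.n_seqs} transcripts, {st.total_nt} nt total, "
      f"mean {st.mean_len:.0f} nt, N50 {st.n50} nt")

# FPKM: fragments per kilobase of transcript per million mapped fragments
value = fpkm(fragments=1500, mapped_total=2_000_000, length_bp=450)
print(f"FPKM(1500 fragments, 2M library, 450 bp) = {value:.1f}")
doubled = fpkm(3000, 4_000_000, 450)
print(f"doubling fragments and library size leaves it unchanged: {doubled:.1f}")

# N50 is the contig length at which contigs that long or longer hold half
# the assembled bases; FPKM normalises counts by transcript length and
# library depth, so it is invariant to proportional scaling.
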