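# Methods

## Scope and data model

venomkit curates venom-gland transcript sets: nucleotide transcripts are
translated on all six frames, the precursor-coding ORF is selected, each
precursor is partitioned into signal peptide / N-propeptide / mature
peptide / amide-donor glycine / C-propeptide, the mature peptide is
classified into a venom family, its theoretical mass is computed, and the
masses are correlated with an experimental proteome list. Two curated
fixtures transcribed from the source study ship with the package: a
111-row precursor table with annotated segments, and a 16-row
transcriptome-vs-proteome mass correlation table. They are the validation
set for every heuristic below.

Segment intervals are disjoint, ordered, and jointly cover the precursor;
the C-propeptide interval starts immediately after the amide-donor glycine
and therefore includes the dibasic residues of a processing motif (the
motif text is reported separately). This keeps the partition invariant
("concatenation reconstructs the precursor") exact.

## ORF selection

ORFs are start-anchored (require ATG) by default because curated venom
precursors begin with methionine; a stop-to-stop mode handles partial
transcripts. Candidates from both strands are ranked by protein length,
ties broken toward the '+' strand and then the lower forward-strand start.
Coordinates are 0-based half-open on the forward strand and cover the
protein only (stop codon excluded). The default length floor is 40 aa:
the shortest complete curated precursors are ~58 aa, and the margin admits
5'-truncated ones. Longest-ORF selection is a convention, not a claim
about biology; multi-ORF transcripts can defeat it.

## Signal cleavage heuristic

Trained signal-peptide predictors are deliberately not reimplemented; a
transparent stand-in is used so every call is auditable. Candidate cuts
`c ∈ [15, 45]` are scored

```
score(c) = mean KD(h-region: 5..c−6)
         + 1.0 · [residues at c−3 and c−1 ∈ {A,G,S,C,T,V}]
         − 0.15 · |c − 24|
```

KD is the Kyte–Doolittle hydropathy index. The mean-hydropathy term alone
systematically prefers the shortest hydrophobic window, so the mild length
prior (centred on the 24-residue mode of curated signals) is essential;
with it, 55/60 full-length curated rows cleave within ±2 residues of the
annotation (36 exactly). Below a best score of 1.5 no signal is called
(poly-acidic N-termini, non-M starts, precursors < 25 aa). Callers can
supply external cleavage calls by segmenting manually; the segmentation
result records the provenance of each boundary in `method_flags`.

## Amidation and propeptides

The amide-donor glycine is recognised in two architectures:

1. **Motif rule** — a `G[KR][KR]` tripeptide 8–25 residues past the
   signal whose downstream remainder is ≥ 20% D/E ends the mature peptide;
   the G donates the amide and the acidic C-propeptide follows. Dipeptide
   `G[KR]` hits are reported by `find_processing_motifs` but do not set
   amidation: every amidated curated motif row uses the tripeptide, and
   dipeptides false-fire on cysteine-rich matures. The acidity threshold
   is 0.20 because one curated amidated row has a C-propeptide at 23% D/E;
   at 0.20 there are no false positives anywhere in the fixture.
2. **Terminal rule** — a precursor-terminal G donates the amide only when
   a cysteine lies within the four preceding residues, i.e. the glycine
   directly follows the cysteine framework. This pattern holds for all six
   amidated terminal-G fixture rows and excludes the isolated terminal
   glycines of partial/enzyme rows. A bare "terminal G or G+basics" rule
   would mislabel four non-amidated rows.

An acidic N-propeptide is called when a 10–30 residue stretch immediately
after the signal ends in R, is ≥ 20% D/E, and is followed by ≥ 20
residues; the shortest qualifying stretch wins so the boundary cannot
drift into an acidic mature region. On the fixture this recovers the one
annotated N-propeptide exactly.

With these rules the pipeline reproduces 111/111 amidation flags on the
curated table. The boundaries of rows the heuristics cannot see (e.g. an
8-residue propeptide ending in Q) are left inside the mature peptide and
flagged.

## Family rules

Rules fire most-specific-first over (cysteine count, length window,
literal motifs): ascaris-type (10 Cys) → agatoxin-like calcin (8 Cys + CC)
→ La1-like (8 Cys, 65–85 aa) → defensin (6 Cys, 36–40 aa, GFGCP) → calcin
(6 Cys, 30–36 aa, CC) → α-KTx (6/8 Cys, 23–42 aa) → NaTx-like (7–8 Cys,
52–84 aa) → β-KTx/scorpine-like (6 Cys, > 50 aa) → DDH-calcin (4 Cys,
33–40 aa) → allergen-like (≥ 180 aa) → NDBP length classes (0 Cys: < 20 /
20–35 / > 35 aa) → venom-protein/other (any remaining Cys-containing
sequence). Motif-bearing rules (defensin, calcin) must precede α-KTx:
their members sit inside the α-KTx envelope and are distinguishable only
by the GFGCP block or the adjacent CC pair of the cystine-knot fold, which
CSα/β α-KTx scaffolds lack. The NaTx window is widened to 7–8 cysteines
because the curated sodium-toxin rows carry an extended C-tail with an
odd (7) cysteine count. Windows around single exemplars are widened
roughly ±10%; quoted ranges (α-KTx 23–42) are kept exact. On curated rows
whose description names a modeled family, 40/42 classify to it; the two
misses are a 2-Cys fragment described as a β-like toxin and a 9-Cys
5'-truncated ascaris-type row.

## Masses

Residue masses are the standard IUPAC monoisotopic table and the classic
ExPASy-style average table (water 18.010565 / 18.01528 Da). Amidation
subtracts 0.98402 / 0.9847 Da; each disulfide subtracts two hydrogens
(2 × 1.007825 / 2 × 1.00794 Da). Bridge count is ⌊Cys/2⌋ with an
odd-count warning. The published correlation table mixes conventions row
by row (verified: its rows variously match average+amidation, mono+
amidation without bridges, and average+amidation with bridges), so
profiles always carry all four variants plus a closest-variant helper;
comparisons against printed values use 0.1 Da. One published row
(printed 4167.7) is not reproducible from its printed sequence under any
convention (off by ~152 Da) and is flagged in the fixture. Average masses
agree with abundance-derived averages (pyteomics) only to ~20 ppm; the
ExPASy convention is the one behind the published values.

## Matching

All theory × experiment pairs within tolerance are reported;
`n_exp_matched` / `n_theory_matched` count masses with ≥ 1 partner, and
each experimental mass is labelled with its nearest theoretical candidate
(ties: smaller |Δ|, then lower theory index). The default tolerance is
±1.0 Da absolute, typical for average-vs-deconvoluted comparisons; the
published table's own pairs deviate by up to 3.5 Da, so its 16/16
correlation is reproduced at ±4.0 Da (14/16 at ±1.0 Da).

## Alignment

Needleman–Wunsch global alignment via Bio.Align.PairwiseAligner with
BLOSUM62, gap open 10, extend 0.5 (scoring unstated in the source;
identity percentages for the closely related pairs quoted are insensitive
to it). Both identity definitions are reported: identical columns over
the alignment length excluding terminal-gap overhang, and over the
shorter sequence. Quoted identities are compared at ±1 percentage point.
Reference calcin sequences (imperatoxin-A, maurocalcin) are packaged as a
transcribed FASTA; the transcript calcin scores 69.7% / 87.9% against
them, matching the quoted 69% / 87%.

## Synthetic data

The generator emulates a venom-gland transcript set with exact ground
truth. Mature peptides come from per-family exemplar scaffolds: cysteine
positions keep the exemplar spacings (run lengths jittered ±1, with
zero-length runs pinned so CC doublets are neither created nor destroyed),
all other positions are redrawn from a mildly hydrophilic background
without cysteine, and each family keeps its diagnostic features and length
window. NDBP-short precursors follow the antimicrobial grammar: 23–24 aa
signal, < 20 aa mature, GKR motif, 31–46 aa C-propeptide at 40% D/E.
Synthetic signals are `M + 4 basic/polar + LIF core + QSDA`, which places
the (−3,−1) bonus only at the true cut; any shifted cut dilutes its
h-region with c-region residues and pays the length prior, so cleavage is
exact by construction. Precursors are redrawn until grammar unambiguity
constraints hold (no decoy motif with acidic remainder, no competing
acidic N-stretch); these constraints mirror the segmentation triggers and
are what make the noiseless 100%-recovery guarantee a property of the
grammar rather than luck.

Reverse transcription samples synonymous codons uniformly, appends a stop
codon and 30–150 nt UTRs, and flips strand with probability ½; transcripts
are redrawn until the planted CDS is the unique longest start-anchored
ORF. The simulated proteome perturbs each amidation-aware,
bridge-subtracted average mass with Gaussian noise (default sd 0.5 Da),
drops peptides with probability 0.1, and assigns uniform retention times
in 10–50 min. The default census is 200 precursors dominated by NDBPs and
α-KTx scaffolds, as in non-Buthidae venom glands, plus optional
housekeeping-like decoys.

What the generator does **not** emulate: assembly artefacts and chimeras,
sequencing error, isoform/allele structure, non-uniform codon usage,
PTMs beyond amidation and disulfides, RT–mass correlation, and realistic
mass-list contamination. Passing the synthetic recovery tests therefore
shows the pipeline's rules are internally exact, not that they are
complete for real venom-gland data — the curated fixture checks carry
that weight.

## Numerical and design choices

* One seeded NumPy generator per synthetic stage (seed, seed+1, ...);
  no global RNG state; identical configs give byte-identical outputs.
* Rejection sampling is capped at 200 draws per record (a failure raises
  rather than silently degrading the guarantee).
* The pipeline's deterministic tie-breaks: ORF (length, strand, start);
  motif (first qualifying in window, extras recorded); N-propeptide
  (shortest qualifying stretch); nearest mass (|Δ|, then index).
* Degenerate inputs: precursors < 25 aa are returned whole as mature and
  flagged; undetermined residues (X) make mass profiles unavailable
  rather than wrong; empty match inputs give empty reports.
* Test problem sizes: 200-precursor synthetic sets, 10³×10³ matcher
  equivalence, 10⁴-peptide mass property sweeps, exhaustive alignment
  enumeration up to length 8 — chosen so the full suite runs in seconds
  while still exercising every guarantee.

## Known limitations

The cleavage heuristic is a stand-in for trained predictors and misses
~8% of curated sites by > 2 residues; boundaries derived from it should
be treated as provisional where no motif corroborates them. Family rules
are envelope-based and will absorb unusual scaffolds into
venom-protein/other; they are not a substitute for homology search.
Longest-ORF selection can pick the wrong frame on bicistronic or
chimeric contigs. Disulfide connectivity (as opposed to count) and PTMs
other than amidation/disulfides are out of scope.
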