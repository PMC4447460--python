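# Rule-based venom family classification for mature peptides.
#
# Rules are evaluated in ascending `priority`; the first rule whose envelope
# (cysteine count, length window, required motifs) contains the peptide fires.
# Envelope widths follow the canonical family descriptions (exact where a range
# is quoted, e.g. alpha-KTx 23-42 aa; widened around single exemplars
# otherwise).  Motif strings are literal subsequences of the mature peptide:
# "CC" marks the adjacent half-cystine pair of knottin-type scaffolds and
# "GFGCP" the defensin amino-terminal block.
rules:
  - family: ascaris-type-inhibitor
    priority: 10
    cys: [10]
    length: [50, 100]
  - family: agatoxin-like-calcin
    priority: 20
    cys: [8]
    length: [38, 55]
    motifs: [CC]
  - family: La1-like
    priority: 30
    cys: [8]
    length: [65, 85]
  - family: defensin
    priority: 40
    cys: [6]
    length: [36, 40]
    motifs: [GFGCP]
  - family: calcin
    priority: 50
    cys: [6]
    length: [30, 36]
    motifs: [CC]
  - family: alpha-KTx
    priority: 60
    cys: [6, 8]
    length: [23, 42]
  - family: NaTx-like
    priority: 70
    cys: [7, 8]
    length: [52, 84]
  - family: scorpine-like/beta-KTx
    priority: 80
    cys: [6]
    length: [51, 110]
  - family: DDH-calcin
    priority: 90
    cys: [4]
    length: [33, 40]
  - family: allergen-like
    priority: 100
    length: [180, 100000]
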