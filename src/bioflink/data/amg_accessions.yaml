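# Default auxiliary-metabolic-gene accession list (KEGG orthologs and
# PFAM domains). Small illustrative core around experimentally grounded
# AMGs (nrdA ribonucleotide reductase, psbA photosystem II D1) plus
# common nucleotide/folate metabolism entries; extend for real surveys.
kegg:
  - K00525   # nrdA, ribonucleoside-diphosphate reductase alpha
  - K02703   # psbA, photosystem II P680 D1
  - K00560   # thyA, thymidylate synthase
  - K00602   # purH, AICAR transformylase
  - K01495   # folE, GTP cyclohydrolase I
  - K00067   # rfbD, dTDP-sugar biosynthesis
pfam:
  - PF00317  # ribonucleotide reductase, all-alpha
  - PF00124  # photosystem II reaction centre
  - PF00303  # thymidylate synthase
  - PF01808  # AICAR transformylase
  - PF01227  # GTP cyclohydrolase I
  - PF04321  # RmlD-like substrate binding
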