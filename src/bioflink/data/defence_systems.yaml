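# Default conserved-domain map: defence system -> required components ->
# PFAM accessions confirming each component. Illustrative starter set; a
# real survey should extend it (the file is plain config, edit freely).
RM:
  methyltransferase: [PF01555, PF02384, PF13651]
  restriction_endonuclease: [PF04313, PF18766]
CRISPR-Cas:
  cas1: [PF01867]
  cas2: [PF09827]
TA:
  toxin: [PF05016, PF02452]
  antitoxin: [PF04221, PF03693]
BREX:
  brxC: [PF10923]
  pglZ: [PF08665]
DISARM:
  drmA: [PF00271]
ABI:
  abiEii: [PF08843]
Zorya:
  zorA: [PF00669]
Hachiman:
  hamA: [PF18742]
Gabija:
  gajA: [PF13175]
Septu:
  ptuA: [PF13304]
Thoeris:
  thsA: [PF13289]
Lamassu:
  lmuA: [PF02463]
Druantia:
  druE: [PF14236]
Wadjet:
  jetC: [PF09660]
Kiwa:
  kwaA: [PF16162]
Shedu:
  sduA: [PF14082]
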