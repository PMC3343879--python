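# Named HLA allele groups. B*35 Px vs PY: Px alleles bind peptides with
# hydrophobic non-tyrosine C-terminal anchor residues, PY alleles require
# tyrosine at peptide position 9.
B35_Px:
  - "B*35:02"
  - "B*35:03"
B35_PY:
  - "B*35:01"
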