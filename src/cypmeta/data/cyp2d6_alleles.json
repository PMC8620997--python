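{
  "gene": "CYP2D6",
  "build": "GRCh37",
  "chrom": "22",
  "gene_start": 42522500,
  "gene_end": 42526883,
  "region_flank": 1000000,
  "notes": "Reconstructed SNV-only definition panel (no CNV/hybrid alleles). Positions are GRCh37. *4 carries 100C>T (rs1065852) plus the 1846G>A splice defect (rs3892097); *10 carries 100C>T alone, so *4 is matched preferentially as the more specific allele."
}
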