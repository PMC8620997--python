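{
  "gene": "CYP2C19",
  "build": "GRCh37",
  "chrom": "10",
  "gene_start": 96522463,
  "gene_end": 96612671,
  "region_flank": 1000000,
  "notes": "Reconstructed core panel: *2 (681G>A splice defect), *3 (636G>A stop), *17 (-806C>T promoter, increased expression). rs12248560 lies upstream of the gene body but inside the 1 Mb extraction flank."
}
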