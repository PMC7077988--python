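# Synthetic default library-design configuration.
#
# The building blocks embed each TF's consensus site (KLF4 with its fifth
# position changed to T, the cloning-compatible variant) in constant 20-bp
# flanks.  These are synthetic stand-ins designed to scan cleanly with the
# bundled synthetic PFMs: exactly one motif hit per block, no cross-TF or
# junction-created hits over all ordered pairs of oriented blocks, and no
# restriction sites.  Replace blocks/motifs with the real published ones to
# reproduce a specific published library.
motifs:
  O: synthetic_OCT4.jaspar
  S: synthetic_SOX2.jaspar
  K: synthetic_KLF4.jaspar
  E: synthetic_ESRRB.jaspar
blocks:
  O: {sequence: CGGGACATGCAAATAGGCCA, site_start: 6, site_length: 8}
  S: {sequence: GGATTTCATTGTTCAATTGA, site_start: 6, site_length: 8}
  K: {sequence: TTTAAGGGGTAAGAGCTGGA, site_start: 5, site_length: 9}
  E: {sequence: CGCAGTCAAGGTCATTGTAG, site_start: 5, site_length: 9}
scaffolds:
  syn:
    template: "CTTCTACTACTAGGGCCCA[SEQ]AAGCTT[FILL]GAATTCTCTAGAC[BC]TGAGCTCTACATGCTAGTTCATG"
    total_length: 150
  genomic:
    template: "GACTTACATTAGGGCCCGT[SEQ]AAGCTT[FILL]GAATTCTCTAGAC[BC]TGAGCTCGGACTACGATACTG"
    total_length: 150
  mini_spacer:
    template: "GACATCAAGATCTGGCCTCGGGGCCC[SEQ]AAGCTTGAATTCTCTAGAC[BC]TGAGCTCTCGCTTCGAGCAGACATGAT"
    total_length: 161
restriction_sites:
  ApaI: GGGCCC
  SacI: GAGCTC
  HindIII: AAGCTT
  EcoRI: GAATTC
  XbaI: TCTAGA
  SpeI: ACTAGT
barcode:
  length: 9
  max_homopolymer: 4
  min_hamming: 2
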