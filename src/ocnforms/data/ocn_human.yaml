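# Mature human osteocalcin site inventory (1-based mature-chain numbering).
# The mature human chain has no Ser or Thr, hence no O-glycosylation sites;
# the residue aligning with mouse S8 is Y12.
disulfide_bonds:
  - [23, 29]
gla_sites: [17, 21, 24]
glycosites: []
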