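# Pool-seq case-control power sweep (full-scale base panel; reduce
# region_bp / replicates for a quick run).
experiment: fig1_power
fig1:
  n_haplotypes: 500
  region_bp: 1000000
  pool_size: 10000
  coverages: [400.0, 1000.0, 5000.0]
  deltas: [0.04, 0.08]
  replicates: 50
  threshold: 5.0
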