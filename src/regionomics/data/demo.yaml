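# Packaged demo configuration: a desk-scale synthetic study with eight
# brain-region-like tissues, two conditions and planted ground truth.
seed: 1

thresholds:
  q_bulk: 0.1
  q_pseudobulk: 0.2
  q_regulon: 0.1
  alpha_proportion: 0.05

modules_k: 8
rrho_regions: [R01, R02]

bulk:
  n_regions: 8
  n_genes: 1000
  n_replicates: 4
  genes_per_module: 40
  effect: 1.0

chip:
  rho: 0.8
  n_replicates: 2

sc:
  regions: [dorDG, venDG]
  n_genes: 800
  n_types: 6
  n_replicates: 5
  cells_per_replicate: 120
  proportion_shift_type: type03
  proportion_shift_fold: 2.0
  module_shift_type: type01
  module_shift_log2fc: 1.0
  regulon_shift_type: type01
  regulon_shift_log2fc: 1.0
  lr_sender: type02
  lr_receiver: type01
  lr_shift_log2fc: 1.0
  min_genes: 200
  max_mito: 0.2
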