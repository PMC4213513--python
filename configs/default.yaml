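seed: 20141014
n_proteins: 100
protein_length:
- 40
- 250
pockets_per_protein:
- 1
- 3
pocket_fraction:
- 0.1
- 0.14
min_pocket_size: 3
mapping_coverage: 0.9
n_samples: 500
cancer_types:
  uterine: 0.16
  skin: 0.14
  colon: 0.12
  stomach: 0.11
  breast: 0.1
  lung adenocarcinoma: 0.09
  head and neck: 0.08
  lung squamous: 0.07
  bladder: 0.07
  blood: 0.06
background_rate_per_residue: 0.05
planted_genes:
- gene: GENE0001
  enrichment_factor: 5.0
  occurrences: 30
class_mix:
  missense: 0.709
  silent: 0.206
  nonsense: 0.051
  indel: 0.034
n_network_genes: 500
n_ppi_edges: 2000
n_tissues: 126
coexpression_boost: 0.8
n_cell_lines: 100
pocket_mutant_prob: 0.12
nonpocket_mutant_prob: 0.22
drugs:
- vinorelbine
- midostaurin
- tipifarnib
ic50_shift: -1.5
ic50_mu: 3.0
ic50_sigma: 1.0
n_patients: 200
hazard_ratio: 2.5
baseline_hazard_per_day: 0.0006666666666666666
censoring_horizon_days: 4000.0
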