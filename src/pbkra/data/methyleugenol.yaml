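name: methyleugenol
mw_parent: 178.2
mw_metabolite: 194.2
log_kow: 3.03
partitions:
  parent:
    fat: 103.0
    liver: 6.2
    richly: 6.2
    slowly: 3.9
  metabolite_liver: 1.4
phase1:
- pathway_id: HE
  product_name: 1'-hydroxymethyleugenol
  phase: 1
  vmax_unscaled: 1.38
  vmax_sd: 0.38
  km: 404.0
  km_sd: 195.0
  protein_basis: microsomal
  is_hydroxylation_route: true
- pathway_id: AP
  product_name: eugenol
  phase: 1
  vmax_unscaled: 0.15
  vmax_sd: 0.02
  km: 13.6
  km_sd: 12.3
  protein_basis: microsomal
  is_hydroxylation_route: false
- pathway_id: EE
  product_name: methyleugenol-2',3'-oxide
  phase: 1
  vmax_unscaled: 0.66
  vmax_sd: 0.11
  km: 23.7
  km_sd: 5.0
  protein_basis: microsomal
  is_hydroxylation_route: false
- pathway_id: HA
  product_name: 3-(3,4-dimethoxyphenyl)-2-propen-1-ol
  phase: 1
  vmax_unscaled: 0.39
  vmax_sd: 0.08
  km: 161.0
  km_sd: 90.0
  protein_basis: microsomal
  is_hydroxylation_route: false
- pathway_id: M5
  product_name: 3-hydroxy-4-methoxyallylbenzene
  phase: 1
  vmax_unscaled: 0.21
  vmax_sd: 0.02
  km: 1097.0
  km_sd: 142.0
  protein_basis: microsomal
  is_hydroxylation_route: false
- pathway_id: M6
  product_name: 2-hydroxy-4,5-dimethoxyallylbenzene
  phase: 1
  vmax_unscaled: 0.1
  vmax_sd: 0.02
  km: 415.0
  km_sd: 84.0
  protein_basis: microsomal
  is_hydroxylation_route: false
phase2:
- pathway_id: HEG
  product_name: 1'-hydroxymethyleugenol glucuronide
  phase: 2
  vmax_unscaled: 0.66
  vmax_sd: 0.087
  km: 2393.0
  km_sd: 486.0
  protein_basis: s9
  is_hydroxylation_route: false
- pathway_id: HES
  product_name: 1'-sulfooxymethyleugenol
  phase: 2
  vmax_unscaled: 0.0009
  vmax_sd: 0.0002
  km: 139.0
  km_sd: 82.0
  protein_basis: s9
  is_hydroxylation_route: false
- pathway_id: HEO
  product_name: 1'-oxomethyleugenol
  phase: 2
  vmax_unscaled: 2.1
  vmax_sd: 1.83
  km: 1774.0
  km_sd: 2997.0
  protein_basis: s9
  is_hydroxylation_route: false
provenance: transcribed target parameter table (human liver kinetics, measured partition coefficients)
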