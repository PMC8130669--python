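name: safrole
mw_parent: 162.19
mw_metabolite: 178.18
log_kow: 3.45
partitions:
  parent:
    fat: 106.0
    liver: 6.65
    richly: 6.65
    slowly: 4.2
    kidney: 6.65
  metabolite_liver: 1.65
phase1:
- pathway_id: DHS
  product_name: dihydroxysafrole
  phase: 1
  vmax_unscaled: 0.07
  vmax_sd: 0.004
  km: 41.0
  km_sd: 10.0
  protein_basis: microsomal
  is_hydroxylation_route: false
- pathway_id: HS
  product_name: 1'-hydroxysafrole
  phase: 1
  vmax_unscaled: 0.15
  vmax_sd: 0.008
  km: 35.0
  km_sd: 10.0
  protein_basis: microsomal
  is_hydroxylation_route: true
- pathway_id: HIS
  product_name: 3'-hydroxysafrole
  phase: 1
  vmax_unscaled: 0.11
  vmax_sd: 0.01
  km: 255.0
  km_sd: 99.0
  protein_basis: microsomal
  is_hydroxylation_route: false
- pathway_id: CHAV
  product_name: dihydroxychavicol
  phase: 1
  vmax_unscaled: 0.85
  vmax_sd: 0.05
  km: 172.0
  km_sd: 30.0
  protein_basis: microsomal
  is_hydroxylation_route: false
phase2:
- pathway_id: HSG
  product_name: 1'-hydroxysafrole glucuronide
  phase: 2
  vmax_unscaled: 0.1
  vmax_sd: 0.006
  km: 1322.0
  km_sd: 208.0
  protein_basis: s9
  is_hydroxylation_route: false
- pathway_id: HSS
  product_name: 1'-sulfooxysafrole
  phase: 2
  vmax_unscaled: 0.017
  vmax_sd: 0.005
  km: 3828.0
  km_sd: 1801.0
  protein_basis: s9
  is_hydroxylation_route: false
- pathway_id: HSO
  product_name: 1'-oxosafrole
  phase: 2
  vmax_unscaled: 7.5
  vmax_sd: 0.4
  km: 549.0
  km_sd: 84.0
  protein_basis: s9
  is_hydroxylation_route: false
provenance: transcribed source parameter table (human liver kinetics, measured partition coefficients); log_kow assumed (not reported with the kinetic table), unused by simulation
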