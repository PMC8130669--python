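name: estragole
mw_parent: 148.2
mw_metabolite: 164.2
log_kow: 3.47
partitions:
  parent:
    fat: 105.0
    liver: 6.5
    richly: 6.5
    slowly: 4.0
  metabolite_liver: 1.6
phase1:
- pathway_id: HE
  product_name: 1'-hydroxyestragole
  phase: 1
  vmax_unscaled: 0.7
  vmax_sd: 0.04
  km: 21.0
  km_sd: 6.0
  protein_basis: microsomal
  is_hydroxylation_route: true
- pathway_id: AP
  product_name: 4-allylphenol
  phase: 1
  vmax_unscaled: 0.4
  vmax_sd: 0.02
  km: 290.0
  km_sd: 28.0
  protein_basis: microsomal
  is_hydroxylation_route: false
- pathway_id: EE
  product_name: estragole-2',3'-oxide
  phase: 1
  vmax_unscaled: 0.9
  vmax_sd: 0.07
  km: 83.0
  km_sd: 17.0
  protein_basis: microsomal
  is_hydroxylation_route: false
- pathway_id: HA
  product_name: 3'-hydroxyanethole
  phase: 1
  vmax_unscaled: 1.4
  vmax_sd: 0.05
  km: 350.0
  km_sd: 20.0
  protein_basis: microsomal
  is_hydroxylation_route: false
- pathway_id: M5
  product_name: fifth phase I metabolite
  phase: 1
  vmax_unscaled: 0.18
  vmax_sd: 0.02
  km: 618.0
  km_sd: 164.0
  protein_basis: microsomal
  is_hydroxylation_route: false
phase2:
- pathway_id: HEG
  product_name: 1'-hydroxyestragole glucuronide
  phase: 2
  vmax_unscaled: 0.29
  vmax_sd: null
  km: 708.0
  km_sd: null
  protein_basis: s9
  is_hydroxylation_route: false
- pathway_id: HES
  product_name: 1'-sulfooxyestragole
  phase: 2
  vmax_unscaled: 0.006
  vmax_sd: 0.005
  km: 727.0
  km_sd: 185.0
  protein_basis: s9
  is_hydroxylation_route: false
- pathway_id: HEO
  product_name: 1'-oxoestragole
  phase: 2
  vmax_unscaled: 3.2
  vmax_sd: 0.88
  km: 345.0
  km_sd: 151.0
  protein_basis: s9
  is_hydroxylation_route: false
provenance: transcribed source parameter table (human liver kinetics, measured partition coefficients)
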