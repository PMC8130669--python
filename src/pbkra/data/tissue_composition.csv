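tissue,lipid_fraction,water_fraction
blood,0.0067,0.83
fat,0.853,0.10
liver,0.042,0.71
richly,0.042,0.71
slowly,0.029,0.76
kidney,0.035,0.77
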