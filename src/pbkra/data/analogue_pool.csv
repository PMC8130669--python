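name,smiles,toolbox_similarity,knime_consensus,has_human_pbk_model,model_validated_in_vivo,model_reproducible,similar_adme,notes
eugenol,COc1cc(CC=C)ccc1O,0.82,,true,false,false,true,human model exists but full code not reported (irreproducible); simulator predicts common 1'-hydroxy route
elemicin,COc1cc(CC=C)cc(OC)c1OC,0.80,0.78,true,false,true,true,human and rodent models built by read-across; not validated with in vivo data
estragole,COc1ccc(CC=C)cc1,0.70,0.66,true,true,true,true,valid and reproducible human model; shared 1'-hydroxylation bioactivation
safrole,C=CCc1ccc2c(c1)OCO2,0.64,0.69,true,true,true,true,valid and reproducible human model; shared 1'-hydroxylation bioactivation
myristicin,COc1cc(CC=C)cc2c1OCO2,0.66,0.58,true,false,true,true,models built by read-across; not validated with in vivo data
apiol,C=CCc1cc2c(c(OC)c1OC)OCO2,,0.49,true,false,true,true,similarity below cut-off; model not validated with in vivo data
isosafrole,CC=Cc1ccc2c(c1)OCO2,,,false,,,,"no PBK model available; similarity below cut-off"
anethole,COc1ccc(C=CC)cc1,,,false,,,,"no PBK model available; similarity below cut-off"
allylbenzene,C=CCc1ccccc1,,,false,,,,"no PBK model available; similarity below cut-off"
methyleugenol,COc1ccc(CC=C)cc1OC,1.00,1.00,true,true,true,true,target chemical; own model used only to check the read-across predictions
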