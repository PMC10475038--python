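metabolite	model_mmol_per_l
acetyl_coa	0.071
oxaloacetate	0.005
citrate	0.184
isocitrate_cisaconitate	0.017
alpha_ketoglutarate	0.031
succinylcoa_succinate	0.720
fumarate	0.488
malate	0.495
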