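metabolite	kind	value_or_low	high	source
acetyl_coa	point	0.0288		CR29
acetyl_coa	point	0.61		CR30
acetyl_coa	point	0.07		CR2
acetyl_coa	point	0.5		CR31
oxaloacetate	point	0.00201		CR29
oxaloacetate	range	0.002	0.006	CR32
oxaloacetate	point	0.005		CR2
citrate	point	0.584		CR29
citrate	point	2		CR30
citrate	point	0.114		CR33
citrate	point	0.4		CR2
citrate	point	0.19		CR34
isocitrate_cisaconitate	point	0.0321		CR29
isocitrate_cisaconitate	range	0.002	0.006	CR35
isocitrate_cisaconitate	point	0.02		CR31
alpha_ketoglutarate	point	0.797		CR29
alpha_ketoglutarate	point	0.44		CR30
alpha_ketoglutarate	point	0.25		CR2
alpha_ketoglutarate	point	0.54		CR36
alpha_ketoglutarate	range	0.004	0.013	CR37
succinylcoa_succinate	point	0.23		CR30
succinylcoa_succinate	point	0.0068		CR29
succinylcoa_succinate	point	0.66		CR36
succinylcoa_succinate	range	0.36	0.91	CR38
fumarate	point	0.485		CR29
fumarate	point	0.12		CR30
fumarate	point	0.124		CR29
fumarate	point	1.94		CR36
malate	point	1.7		CR30
malate	point	1.39		CR29
malate	point	0.495		CR36
malate	point	0.87		CR34
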