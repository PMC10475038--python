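[network]
name = "default-energy-metabolism"
version = "approximate-1"

[pool.glucose]
name = "Glucose"
initial_mmol_per_l = 5.0
packet_size_mmol_per_l = 0.005
pathways = ["glycolysis"]
compartment = "cytosol"

[pool.g6p]
name = "Glucose 6-phosphate"
initial_mmol_per_l = 0.083
packet_size_mmol_per_l = 8.3e-05
pathways = ["glycolysis", "ppp"]
compartment = "cytosol"

[pool.f6p]
name = "Fructose 6-phosphate"
initial_mmol_per_l = 0.03
packet_size_mmol_per_l = 2.9999999999999997e-05
pathways = ["glycolysis", "ppp"]
compartment = "cytosol"

[pool.fbp]
name = "Fructose 1,6-bisphosphate"
initial_mmol_per_l = 0.031
packet_size_mmol_per_l = 3.1e-05
pathways = ["glycolysis"]
compartment = "cytosol"

[pool.dhap]
name = "Dihydroxyacetone phosphate"
initial_mmol_per_l = 0.14
packet_size_mmol_per_l = 0.00014000000000000001
pathways = ["glycolysis"]
compartment = "cytosol"

[pool.gap]
name = "Glyceraldehyde 3-phosphate"
initial_mmol_per_l = 0.019
packet_size_mmol_per_l = 1.9e-05
pathways = ["glycolysis", "ppp"]
compartment = "cytosol"

[pool.bpg13]
name = "1,3-bisphosphoglycerate"
initial_mmol_per_l = 0.004
packet_size_mmol_per_l = 4e-06
pathways = ["glycolysis"]
compartment = "cytosol"

[pool.pg3]
name = "3-phosphoglycerate"
initial_mmol_per_l = 0.12
packet_size_mmol_per_l = 0.00011999999999999999
pathways = ["glycolysis"]
compartment = "cytosol"

[pool.pg2]
name = "2-phosphoglycerate"
initial_mmol_per_l = 0.03
packet_size_mmol_per_l = 2.9999999999999997e-05
pathways = ["glycolysis"]
compartment = "cytosol"

[pool.pep]
name = "Phosphoenolpyruvate"
initial_mmol_per_l = 0.023
packet_size_mmol_per_l = 2.3e-05
pathways = ["glycolysis"]
compartment = "cytosol"

[pool.pyruvate]
name = "Pyruvate"
initial_mmol_per_l = 0.1
packet_size_mmol_per_l = 0.0001
pathways = ["glycolysis", "shared"]
compartment = "cytosol"

[pool.lactate]
name = "Lactate"
initial_mmol_per_l = 1.5
packet_size_mmol_per_l = 0.0015
pathways = ["shared"]
compartment = "cytosol"

[pool.alanine]
name = "Alanine"
initial_mmol_per_l = 0.5
packet_size_mmol_per_l = 0.0005
pathways = ["shared"]
compartment = "cytosol"

[pool.g1p]
name = "Glucose 1-phosphate"
initial_mmol_per_l = 0.06
packet_size_mmol_per_l = 5.9999999999999995e-05
pathways = ["shared"]
compartment = "cytosol"

[pool.g3p]
name = "Glycerol 3-phosphate"
initial_mmol_per_l = 0.16
packet_size_mmol_per_l = 0.00016
pathways = ["shared"]
compartment = "cytosol"

[pool.pgl6]
name = "6-phosphogluconolactone"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["ppp"]
compartment = "cytosol"

[pool.pgc6]
name = "6-phosphogluconate"
initial_mmol_per_l = 0.02
packet_size_mmol_per_l = 2e-05
pathways = ["ppp"]
compartment = "cytosol"

[pool.ru5p]
name = "Ribulose 5-phosphate"
initial_mmol_per_l = 0.012
packet_size_mmol_per_l = 1.2e-05
pathways = ["ppp"]
compartment = "cytosol"

[pool.r5p]
name = "Ribose 5-phosphate"
initial_mmol_per_l = 0.02
packet_size_mmol_per_l = 2e-05
pathways = ["ppp"]
compartment = "cytosol"

[pool.x5p]
name = "Xylulose 5-phosphate"
initial_mmol_per_l = 0.02
packet_size_mmol_per_l = 2e-05
pathways = ["ppp"]
compartment = "cytosol"

[pool.s7p]
name = "Sedoheptulose 7-phosphate"
initial_mmol_per_l = 0.07
packet_size_mmol_per_l = 7.000000000000001e-05
pathways = ["ppp"]
compartment = "cytosol"

[pool.e4p]
name = "Erythrose 4-phosphate"
initial_mmol_per_l = 0.004
packet_size_mmol_per_l = 4e-06
pathways = ["ppp"]
compartment = "cytosol"

[pool.prpp]
name = "Phosphoribosyl pyrophosphate"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["ppp", "shared"]
compartment = "cytosol"

[pool.aspartate]
name = "Aspartate"
initial_mmol_per_l = 0.5
packet_size_mmol_per_l = 0.0005
pathways = ["shared"]
compartment = "cytosol"

[pool.glutamate]
name = "Glutamate"
initial_mmol_per_l = 3.0
packet_size_mmol_per_l = 0.003
pathways = ["shared"]
compartment = "cytosol"

[pool.glutamine]
name = "Glutamine"
initial_mmol_per_l = 4.0
packet_size_mmol_per_l = 0.004
pathways = ["shared"]
compartment = "cytosol"

[pool.acetyl_coa]
name = "Acetyl-CoA"
initial_mmol_per_l = 0.07
packet_size_mmol_per_l = 7.000000000000001e-05
pathways = ["shared", "tca"]
compartment = "mitochondrion"

[pool.oxaloacetate]
name = "Oxaloacetate"
initial_mmol_per_l = 0.006
packet_size_mmol_per_l = 6e-06
pathways = ["tca"]
compartment = "mitochondrion"

[pool.citrate]
name = "Citrate"
initial_mmol_per_l = 0.19
packet_size_mmol_per_l = 0.00019
pathways = ["tca"]
compartment = "mitochondrion"

[pool.isocitrate_cisaconitate]
name = "Isocitrate cis-aconitate"
initial_mmol_per_l = 0.02
packet_size_mmol_per_l = 2e-05
lumped_members = ["isocitrate", "cis-aconitate"]
pathways = ["tca"]
compartment = "mitochondrion"

[pool.alpha_ketoglutarate]
name = "alpha-ketoglutarate"
initial_mmol_per_l = 0.03
packet_size_mmol_per_l = 2.9999999999999997e-05
pathways = ["tca"]
compartment = "mitochondrion"

[pool.succinylcoa_succinate]
name = "Succinyl-CoA succinate"
initial_mmol_per_l = 0.73
packet_size_mmol_per_l = 0.00073
lumped_members = ["succinyl-CoA", "succinate"]
pathways = ["tca"]
compartment = "mitochondrion"

[pool.fumarate]
name = "Fumarate"
initial_mmol_per_l = 0.485
packet_size_mmol_per_l = 0.00048499999999999997
pathways = ["tca"]
compartment = "mitochondrion"

[pool.malate]
name = "Malate"
initial_mmol_per_l = 0.495
packet_size_mmol_per_l = 0.000495
pathways = ["tca"]
compartment = "mitochondrion"

[pool.palmitate]
name = "Palmitate"
initial_mmol_per_l = 0.3
packet_size_mmol_per_l = 0.0003
pathways = ["beta_oxidation"]
compartment = "cytosol"

[pool.pcoa]
name = "Palmitoyl-CoA"
initial_mmol_per_l = 0.05
packet_size_mmol_per_l = 5e-05
pathways = ["beta_oxidation"]
compartment = "cytosol"

[pool.pcar]
name = "Palmitoyl-carnitine"
initial_mmol_per_l = 0.03
packet_size_mmol_per_l = 2.9999999999999997e-05
pathways = ["beta_oxidation"]
compartment = "cytosol"

[pool.acyl16]
name = "C16 acyl-CoA"
initial_mmol_per_l = 0.02
packet_size_mmol_per_l = 2e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.enoyl16]
name = "C16 enoyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.hacyl16]
name = "C16 3-hydroxyacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.kacyl16]
name = "C16 3-ketoacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.acyl14]
name = "C14 acyl-CoA"
initial_mmol_per_l = 0.02
packet_size_mmol_per_l = 2e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.enoyl14]
name = "C14 enoyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.hacyl14]
name = "C14 3-hydroxyacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.kacyl14]
name = "C14 3-ketoacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.acyl12]
name = "C12 acyl-CoA"
initial_mmol_per_l = 0.02
packet_size_mmol_per_l = 2e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.enoyl12]
name = "C12 enoyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.hacyl12]
name = "C12 3-hydroxyacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.kacyl12]
name = "C12 3-ketoacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.acyl10]
name = "C10 acyl-CoA"
initial_mmol_per_l = 0.02
packet_size_mmol_per_l = 2e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.enoyl10]
name = "C10 enoyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.hacyl10]
name = "C10 3-hydroxyacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.kacyl10]
name = "C10 3-ketoacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.acyl8]
name = "C8 acyl-CoA"
initial_mmol_per_l = 0.02
packet_size_mmol_per_l = 2e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.enoyl8]
name = "C8 enoyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.hacyl8]
name = "C8 3-hydroxyacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.kacyl8]
name = "C8 3-ketoacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.acyl6]
name = "C6 acyl-CoA"
initial_mmol_per_l = 0.02
packet_size_mmol_per_l = 2e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.enoyl6]
name = "C6 enoyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.hacyl6]
name = "C6 3-hydroxyacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.kacyl6]
name = "C6 3-ketoacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.acyl4]
name = "C4 acyl-CoA"
initial_mmol_per_l = 0.02
packet_size_mmol_per_l = 2e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.enoyl4]
name = "C4 enoyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.hacyl4]
name = "C4 3-hydroxyacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[pool.kacyl4]
name = "C4 3-ketoacyl-CoA"
initial_mmol_per_l = 0.01
packet_size_mmol_per_l = 1e-05
pathways = ["beta_oxidation"]
compartment = "mitochondrion"

[reaction.hk]
enzyme = "hexokinase"
substrates = ["glucose"]
products = ["g6p"]
vf = 0.0012575757575757577
k_s1 = 5.0
k_p1 = 0.083

[reaction.pgi]
enzyme = "glucose-6-phosphate isomerase"
substrates = ["g6p"]
products = ["f6p"]
vf = 0.0001818181818181818
k_s1 = 0.083
k_p1 = 0.03

[reaction.pfk]
enzyme = "phosphofructokinase-1"
substrates = ["f6p"]
products = ["fbp"]
vf = 0.0003636363636363636
k_s1 = 0.03
k_p1 = 0.031

[reaction.ald]
enzyme = "fructose-bisphosphate aldolase"
substrates = ["fbp"]
products = ["dhap", "gap"]
vf = 0.00046060606060606066
k_s1 = 0.031
k_p1 = 0.14
k_p2 = 0.019

[reaction.tpi]
enzyme = "triose-phosphate isomerase"
substrates = ["dhap"]
products = ["gap"]
vf = 0.00017272727272727275
k_s1 = 0.14
k_p1 = 0.019

[reaction.gapdh]
enzyme = "glyceraldehyde-3-phosphate dehydrogenase"
substrates = ["gap"]
products = ["bpg13"]
vf = 9.696969696969698e-05
k_s1 = 0.019
k_p1 = 0.004

[reaction.pgk]
enzyme = "phosphoglycerate kinase"
substrates = ["bpg13"]
products = ["pg3"]
vf = 9.696969696969698e-05
k_s1 = 0.004
k_p1 = 0.12

[reaction.pgam]
enzyme = "phosphoglycerate mutase"
substrates = ["pg3"]
products = ["pg2"]
vf = 0.0007272727272727272
k_s1 = 0.12
k_p1 = 0.03

[reaction.eno]
enzyme = "enolase"
substrates = ["pg2"]
products = ["pep"]
vf = 0.0005575757575757576
k_s1 = 0.03
k_p1 = 0.023

[reaction.pk]
enzyme = "pyruvate kinase"
substrates = ["pep"]
products = ["pyruvate"]
vf = 0.0005575757575757576
k_s1 = 0.023
k_p1 = 0.1

[reaction.pgm1]
enzyme = "phosphoglucomutase"
substrates = ["g6p"]
products = ["g1p"]
vf = 0.0001818181818181818
k_s1 = 0.083
k_p1 = 0.06

[reaction.g3pdh]
enzyme = "glycerol-3-phosphate dehydrogenase"
substrates = ["dhap"]
products = ["g3p"]
vf = 0.00042424242424242425
k_s1 = 0.14
k_p1 = 0.16

[reaction.ldh]
enzyme = "lactate dehydrogenase"
substrates = ["pyruvate"]
products = ["lactate"]
vf = 0.0003030303030303031
k_s1 = 0.1
k_p1 = 1.5

[reaction.alt]
enzyme = "alanine transaminase"
substrates = ["pyruvate"]
products = ["alanine"]
vf = 0.0003030303030303031
k_s1 = 0.1
k_p1 = 0.5

[reaction.pdh]
enzyme = "pyruvate dehydrogenase"
substrates = ["pyruvate"]
products = ["acetyl_coa"]
vf = 0.0010606060606060607
k_s1 = 0.1
k_p1 = 0.07

[reaction.pc]
enzyme = "pyruvate carboxylase"
substrates = ["pyruvate"]
products = ["oxaloacetate"]
vf = 3.636363636363637e-05
k_s1 = 0.1
k_p1 = 0.006

[reaction.me1]
enzyme = "malic enzyme"
substrates = ["malate"]
products = ["pyruvate"]
vf = 0.0003030303030303031
k_s1 = 0.495
k_p1 = 0.1

[reaction.g6pd]
enzyme = "glucose-6-phosphate dehydrogenase"
substrates = ["g6p"]
products = ["pgl6"]
vf = 6.060606060606062e-05
k_s1 = 0.083
k_p1 = 0.01

[reaction.pgls]
enzyme = "6-phosphogluconolactonase"
substrates = ["pgl6"]
products = ["pgc6"]
vf = 6.060606060606062e-05
k_s1 = 0.01
k_p1 = 0.02

[reaction.pgd]
enzyme = "6-phosphogluconate dehydrogenase"
substrates = ["pgc6"]
products = ["ru5p"]
vf = 7.272727272727274e-05
k_s1 = 0.02
k_p1 = 0.012

[reaction.rpi]
enzyme = "ribose-5-phosphate isomerase"
substrates = ["ru5p"]
products = ["r5p"]
vf = 3.636363636363637e-05
k_s1 = 0.012
k_p1 = 0.02

[reaction.rpe]
enzyme = "ribulose-5-phosphate epimerase"
substrates = ["ru5p"]
products = ["x5p"]
vf = 3.636363636363637e-05
k_s1 = 0.012
k_p1 = 0.02

[reaction.tkt1]
enzyme = "transketolase"
substrates = ["r5p", "x5p"]
products = ["s7p", "gap"]
vf = 0.00017272727272727275
k_s1 = 0.02
k_s2 = 0.02
k_p1 = 0.07
k_p2 = 0.019

[reaction.tal]
enzyme = "transaldolase"
substrates = ["s7p", "gap"]
products = ["e4p", "f6p"]
vf = 3.6363636363636364e-05
k_s1 = 0.07
k_s2 = 0.019
k_p1 = 0.004
k_p2 = 0.03

[reaction.tkt2]
enzyme = "transketolase"
substrates = ["x5p", "e4p"]
products = ["f6p", "gap"]
vf = 3.6363636363636364e-05
k_s1 = 0.02
k_s2 = 0.004
k_p1 = 0.03
k_p2 = 0.019

[reaction.prpps]
enzyme = "PRPP synthetase"
substrates = ["r5p"]
products = ["prpp"]
vf = 3.030303030303031e-05
k_s1 = 0.02
k_p1 = 0.01

[reaction.cs]
enzyme = "citrate synthase"
substrates = ["acetyl_coa", "oxaloacetate"]
products = ["citrate"]
vf = 0.0003454545454545455
k_s1 = 0.07
k_s2 = 0.006
k_p1 = 0.19

[reaction.acn]
enzyme = "aconitase"
substrates = ["citrate"]
products = ["isocitrate_cisaconitate"]
vf = 0.0004545454545454546
k_s1 = 0.19
k_p1 = 0.02

[reaction.idh]
enzyme = "isocitrate dehydrogenase"
substrates = ["isocitrate_cisaconitate"]
products = ["alpha_ketoglutarate"]
vf = 0.0004545454545454546
k_s1 = 0.02
k_p1 = 0.03

[reaction.akgdh]
enzyme = "alpha-ketoglutarate dehydrogenase"
substrates = ["alpha_ketoglutarate"]
products = ["succinylcoa_succinate"]
vf = 0.0007727272727272728
k_s1 = 0.03
k_p1 = 0.73

[reaction.sdh]
enzyme = "succinate dehydrogenase"
substrates = ["succinylcoa_succinate"]
products = ["fumarate"]
vf = 0.01249242424242424
k_s1 = 0.73
k_p1 = 0.485

[reaction.fh]
enzyme = "fumarase"
substrates = ["fumarate"]
products = ["malate"]
vf = 0.01249242424242424
k_s1 = 0.485
k_p1 = 0.495

[reaction.mdh]
enzyme = "malate dehydrogenase"
substrates = ["malate"]
products = ["oxaloacetate"]
vf = 0.00013636363636363634
k_s1 = 0.495
k_p1 = 0.006

[reaction.acl]
enzyme = "ATP-citrate lyase"
substrates = ["citrate"]
products = ["oxaloacetate", "acetyl_coa"]
vf = 3.636363636363637e-05
k_s1 = 0.19
k_p1 = 0.006
k_p2 = 0.07

[reaction.ast]
enzyme = "aspartate transaminase"
substrates = ["oxaloacetate"]
products = ["aspartate"]
vf = 1.8181818181818185e-05
k_s1 = 0.006
k_p1 = 0.5

[reaction.gls]
enzyme = "glutaminase"
substrates = ["glutamine"]
products = ["glutamate"]
vf = 0.009090909090909092
k_s1 = 4.0
k_p1 = 3.0

[reaction.gdh]
enzyme = "glutamate dehydrogenase"
substrates = ["glutamate"]
products = ["alpha_ketoglutarate"]
vf = 9.09090909090909e-05
k_s1 = 3.0
k_p1 = 0.03

[reaction.acs]
enzyme = "acyl-CoA synthetase"
substrates = ["palmitate"]
products = ["pcoa"]
vf = 0.00015151515151515154
k_s1 = 0.3
k_p1 = 0.05

[reaction.cpt1]
enzyme = "carnitine palmitoyltransferase I"
substrates = ["pcoa"]
products = ["pcar"]
vf = 9.09090909090909e-05
k_s1 = 0.05
k_p1 = 0.03

[reaction.cpt2]
enzyme = "carnitine palmitoyltransferase II"
substrates = ["pcar"]
products = ["acyl16"]
vf = 6.060606060606062e-05
k_s1 = 0.03
k_p1 = 0.02

[reaction.acad16]
enzyme = "acyl-CoA dehydrogenase (C16)"
substrates = ["acyl16"]
products = ["enoyl16"]
vf = 3.030303030303031e-05
k_s1 = 0.02
k_p1 = 0.01

[reaction.ech16]
enzyme = "enoyl-CoA hydratase (C16)"
substrates = ["enoyl16"]
products = ["hacyl16"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.hadh16]
enzyme = "3-hydroxyacyl-CoA dehydrogenase (C16)"
substrates = ["hacyl16"]
products = ["kacyl16"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.thio16]
enzyme = "3-ketoacyl-CoA thiolase (C16)"
substrates = ["kacyl16"]
products = ["acyl14", "acetyl_coa"]
vf = 6.060606060606062e-05
k_s1 = 0.01
k_p1 = 0.02
k_p2 = 0.07

[reaction.acad14]
enzyme = "acyl-CoA dehydrogenase (C14)"
substrates = ["acyl14"]
products = ["enoyl14"]
vf = 3.030303030303031e-05
k_s1 = 0.02
k_p1 = 0.01

[reaction.ech14]
enzyme = "enoyl-CoA hydratase (C14)"
substrates = ["enoyl14"]
products = ["hacyl14"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.hadh14]
enzyme = "3-hydroxyacyl-CoA dehydrogenase (C14)"
substrates = ["hacyl14"]
products = ["kacyl14"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.thio14]
enzyme = "3-ketoacyl-CoA thiolase (C14)"
substrates = ["kacyl14"]
products = ["acyl12", "acetyl_coa"]
vf = 6.060606060606062e-05
k_s1 = 0.01
k_p1 = 0.02
k_p2 = 0.07

[reaction.acad12]
enzyme = "acyl-CoA dehydrogenase (C12)"
substrates = ["acyl12"]
products = ["enoyl12"]
vf = 3.030303030303031e-05
k_s1 = 0.02
k_p1 = 0.01

[reaction.ech12]
enzyme = "enoyl-CoA hydratase (C12)"
substrates = ["enoyl12"]
products = ["hacyl12"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.hadh12]
enzyme = "3-hydroxyacyl-CoA dehydrogenase (C12)"
substrates = ["hacyl12"]
products = ["kacyl12"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.thio12]
enzyme = "3-ketoacyl-CoA thiolase (C12)"
substrates = ["kacyl12"]
products = ["acyl10", "acetyl_coa"]
vf = 6.060606060606062e-05
k_s1 = 0.01
k_p1 = 0.02
k_p2 = 0.07

[reaction.acad10]
enzyme = "acyl-CoA dehydrogenase (C10)"
substrates = ["acyl10"]
products = ["enoyl10"]
vf = 3.030303030303031e-05
k_s1 = 0.02
k_p1 = 0.01

[reaction.ech10]
enzyme = "enoyl-CoA hydratase (C10)"
substrates = ["enoyl10"]
products = ["hacyl10"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.hadh10]
enzyme = "3-hydroxyacyl-CoA dehydrogenase (C10)"
substrates = ["hacyl10"]
products = ["kacyl10"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.thio10]
enzyme = "3-ketoacyl-CoA thiolase (C10)"
substrates = ["kacyl10"]
products = ["acyl8", "acetyl_coa"]
vf = 6.060606060606062e-05
k_s1 = 0.01
k_p1 = 0.02
k_p2 = 0.07

[reaction.acad8]
enzyme = "acyl-CoA dehydrogenase (C8)"
substrates = ["acyl8"]
products = ["enoyl8"]
vf = 3.030303030303031e-05
k_s1 = 0.02
k_p1 = 0.01

[reaction.ech8]
enzyme = "enoyl-CoA hydratase (C8)"
substrates = ["enoyl8"]
products = ["hacyl8"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.hadh8]
enzyme = "3-hydroxyacyl-CoA dehydrogenase (C8)"
substrates = ["hacyl8"]
products = ["kacyl8"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.thio8]
enzyme = "3-ketoacyl-CoA thiolase (C8)"
substrates = ["kacyl8"]
products = ["acyl6", "acetyl_coa"]
vf = 6.060606060606062e-05
k_s1 = 0.01
k_p1 = 0.02
k_p2 = 0.07

[reaction.acad6]
enzyme = "acyl-CoA dehydrogenase (C6)"
substrates = ["acyl6"]
products = ["enoyl6"]
vf = 3.030303030303031e-05
k_s1 = 0.02
k_p1 = 0.01

[reaction.ech6]
enzyme = "enoyl-CoA hydratase (C6)"
substrates = ["enoyl6"]
products = ["hacyl6"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.hadh6]
enzyme = "3-hydroxyacyl-CoA dehydrogenase (C6)"
substrates = ["hacyl6"]
products = ["kacyl6"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.thio6]
enzyme = "3-ketoacyl-CoA thiolase (C6)"
substrates = ["kacyl6"]
products = ["acyl4", "acetyl_coa"]
vf = 6.060606060606062e-05
k_s1 = 0.01
k_p1 = 0.02
k_p2 = 0.07

[reaction.acad4]
enzyme = "acyl-CoA dehydrogenase (C4)"
substrates = ["acyl4"]
products = ["enoyl4"]
vf = 3.030303030303031e-05
k_s1 = 0.02
k_p1 = 0.01

[reaction.ech4]
enzyme = "enoyl-CoA hydratase (C4)"
substrates = ["enoyl4"]
products = ["hacyl4"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.hadh4]
enzyme = "3-hydroxyacyl-CoA dehydrogenase (C4)"
substrates = ["hacyl4"]
products = ["kacyl4"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.01

[reaction.thio4]
enzyme = "3-ketoacyl-CoA thiolase (C4)"
substrates = ["kacyl4"]
products = ["acetyl_coa"]
vf = 3.030303030303031e-05
k_s1 = 0.01
k_p1 = 0.07

[flow.bal_lactate]
pool = "lactate"
coefficient = -0.0015
tunable = true

[flow.bal_alanine]
pool = "alanine"
coefficient = -0.0005
tunable = true

[flow.bal_g1p]
pool = "g1p"
coefficient = -5.9999999999999995e-05
tunable = true

[flow.bal_g3p]
pool = "g3p"
coefficient = -0.00016
tunable = true

[flow.bal_r5p]
pool = "r5p"
coefficient = 2e-05
tunable = true

[flow.bal_x5p]
pool = "x5p"
coefficient = 2e-05
tunable = true

[flow.bal_prpp]
pool = "prpp"
coefficient = -1e-05
tunable = true

[flow.bal_aspartate]
pool = "aspartate"
coefficient = -0.0005
tunable = true

[flow.bal_glutamine]
pool = "glutamine"
coefficient = 0.004
tunable = true

[flow.bal_acetyl_coa]
pool = "acetyl_coa"
coefficient = -0.0002450000000000001
tunable = true

[flow.bal_citrate]
pool = "citrate"
coefficient = -0.0001900000000000001
tunable = true

[flow.bal_palmitate]
pool = "palmitate"
coefficient = 0.0003
tunable = true
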