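phylotype	Cipr	Sulf	Trim	SS	Ac	DMSO
Hydrogenophaga_sp	2	2	3	15	18	19
Acidovorax_sp	nd	nd	nd	6	3	4
Betaproteobacterium_sp	nd	nd	nd	2	2	2
Bacteroidetes_bacterium	nd	nd	nd	3	2	nd
Cyanobacterium_sp	nd	nd	nd	4	5	5
Cardinium_endosymbiont	24	20	22	nd	nd	nd
Phyllobacteriaceae_sp	2	4	2	nd	nd	nd
Achromobacter_sp	2	4	3	nd	nd	nd
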