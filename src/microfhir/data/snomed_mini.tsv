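#system=http://snomed.info/sct
#version=fixture-1
code	display	parent_codes
138875005	SNOMED CT Concept (fixture root)	
410607006	Organism (organism)	138875005
362981000	Qualifier value (qualifier value)	138875005
71388002	Procedure (procedure)	138875005
363787002	Observable entity (observable entity)	138875005
4341000179107	Microbiology report (record artifact)	138875005
409822003	Domain Bacteria (organism)	410607006
87172008	Gram-negative bacterium (organism)	409822003
112283007	Escherichia coli (organism)	87172008
56415008	Klebsiella pneumoniae (organism)	87172008
52499004	Pseudomonas aeruginosa (organism)	87172008
990000301	Pseudomonas aeruginosa, mucoid phenotype (organism) [synthetic fixture concept]	52499004
91288006	Acinetobacter baumannii (organism)	87172008
3092008	Staphylococcus aureus (organism)	409822003
49872002	Virus (organism)	410607006
407479009	Influenza A virus (organism)	49872002
84676004	Prion (organism)	410607006
414561005	Kingdom Fungi (organism)	410607006
53326005	Candida albicans (organism)	414561005
370570004	Kingdom Protozoa (organism)	410607006
30020004	Plasmodium falciparum (organism)	370570004
243387004	Domain Archaea (organism)	410607006
990000101	Toy archaeon (organism) [synthetic fixture concept]	243387004
387961004	Kingdom Animalia (organism)	410607006
990000102	Toy mite (organism) [synthetic fixture concept]	387961004
414261007	Kingdom Plantae (organism)	410607006
990000103	Toy plant (organism) [synthetic fixture concept]	414261007
770557006	Kingdom Viridiplantae (organism)	410607006
990000104	Toy green alga (organism) [synthetic fixture concept]	770557006
414061000	Slime mold (organism)	410607006
990000105	Toy slime mold (organism) [synthetic fixture concept]	414061000
409793007	Antimicrobial resistant bacteria (organism)	409822003
707497007	Carbapenem resistant bacteria (organism)	409793007
726492000	Carbapenem resistant Pseudomonas aeruginosa (organism)	707497007
115329001	Methicillin resistant Staphylococcus aureus (organism)	409793007
409795000	Antimicrobial resistant virus (organism)	49872002
409794001	Antimicrobial resistant fungi (organism)	414561005
260373001	Detected (qualifier value)	362981000
260415000	Not detected (qualifier value)	362981000
419984006	Inconclusive (qualifier value)	362981000
10828004	Positive (qualifier value)	362981000
260408008	Weakly positive (qualifier value)	362981000
260385009	Negative (qualifier value)	362981000
75540009	High (qualifier value)	362981000
62482003	Low (qualifier value)	362981000
260347006	Present + out of ++++ (qualifier value)	362981000
260348001	Present ++ out of ++++ (qualifier value)	362981000
260349009	Present +++ out of ++++ (qualifier value)	362981000
260350009	Present ++++ out of ++++ (qualifier value)	362981000
117259009	Microscopy (procedure)	71388002
58586006	Microbial ova-parasite examination (procedure)	71388002
117023006	Thick film peripheral blood smear (procedure)	71388002
408195004	Thick film for malarial parasites (procedure)	71388002
117024000	Thin film peripheral blood smear method (procedure)	71388002
67047002	Microbial wet smear (procedure)	71388002
27318003	Potassium hydroxide preparation (procedure)	71388002
104157003	Light microscopy (procedure)	71388002
73512001	Electron microscopic study (procedure)	71388002
127790008	Staining method (procedure)	71388002
67122001	Acid fast stain method (procedure)	127790008
990000201	Toy Gram stain method (procedure) [synthetic fixture concept]	127790008
990000202	Toy fluorescent acid fast stain (procedure) [synthetic fixture concept]	67122001
398545005	Nucleic acid assay (procedure)	71388002
9718006	Polymerase chain reaction analysis (procedure)	71388002
25231800	Immunology laboratory test (procedure)	71388002
77559007	Immunologic avidity, function (observable entity)	363787002
1285113001	Type of antimicrobial resistant organism (observable entity)	363787002
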