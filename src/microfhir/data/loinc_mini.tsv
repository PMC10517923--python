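#system=http://loinc.org
#version=fixture-1
code	display	property	method	class	component
18725-2	Microbiology studies (set)			PANEL.MICRO	
11475-1	Microorganism identified in Specimen by Culture	Prid	Organism specific culture	MICRO	Microorganism identified
49223-1	Colony count [#/volume] in Unspecified specimen by Visual count	NCnc	Visual count	MICRO	Colony count
564-5	Colony count [#] in Unspecified specimen by Visual count	Num	Visual count	MICRO	Colony count
38436-2	Colony count [#/mass] in Unspecified specimen by Visual count	NCnc	Visual count	MICRO	Colony count
20774-6	Colony count [Units/volume] in Unspecified specimen by Visual count	ACnc	Visual count	MICRO	Colony count
18945-6	Methicillin [Susceptibility]	Susc		ABXBACT	Methicillin
18969-1	Piperacillin [Susceptibility] [synthetic fixture code]	Susc		ABXBACT	Piperacillin
18893-8	Ceftazidime [Susceptibility] [synthetic fixture code]	Susc	MIC	ABXBACT	Ceftazidime
18879-7	Cefotaxime [Susceptibility] [synthetic fixture code]	Susc		ABXBACT	Cefotaxime
18932-4	Imipenem [Susceptibility] [synthetic fixture code]	Susc	MIC	ABXBACT	Imipenem
18943-1	Meropenem [Susceptibility] [synthetic fixture code]	Susc		ABXBACT	Meropenem
18906-8	Ciprofloxacin [Susceptibility] [synthetic fixture code]	Susc		ABXBACT	Ciprofloxacin
99998-9	Example agent [Susceptibility] by Genotyping [synthetic fixture code]	Susc	Genotyping	ABXBACT	Example agent
92253-4	Microorganism identified in Isolate or Specimen by Molecular genetics method	Prid	Molgen	MICRO	Microorganism identified
75371-5	Bartlett score of Sputum Qualitative by Light microscopy	Nom	Light microscopy	MICRO	Bartlett score
43391-2	Bacterial vaginosis score	Num		MICRO	Bacterial vaginosis score
99780-9	Multidrug resistant Gram-negative organism classification [Type]	Type		MICRO	MRGN classification
92251-8	Microorganism gene detected [Presence] by Molecular method	PrThr	Molgen	MICRO	Microorganism gene
92246-8	Microorganism resistance mutation detected [Presence] by Molecular method	PrThr	Molgen	MICRO	Resistance mutation
72421-1	Vancomycin resistance vanB gene [Presence] by Molecular method	PrThr	Molgen	ABXBACT	vanB gene
49617-4	Vancomycin resistance vanA gene [Presence] by Molecular method [synthetic fixture code]	Prid	Molgen	ABXBACT	vanA gene
99997-1	Carbapenemase blaKPC gene [Presence] by Molecular method [synthetic fixture code]	PrThr	Molgen	ABXBACT	blaKPC gene
88603-6	Adenovirus Ag [Presence] in Lower respiratory specimen by Immunoassay	PrThr	IA	MICRO	Adenovirus Ag
5221-7	Borrelia burgdorferi Ab [Presence] in Serum by Immunofluorescence [synthetic fixture code]	PrThr	IF	MICRO	Borrelia burgdorferi Ab
99996-3	Clostridioides difficile toxin A+B [Presence] in Stool [synthetic fixture code]	PrThr	IA	MICRO	Toxin A+B
99995-5	Shiga toxin [Presence] in Stool [synthetic fixture code]	Prid	IA	MICRO	Shiga toxin
92894-5	Microbiology - bacterial studies			PANEL.MICRO	
92893-7	Microbiology - viral studies			PANEL.MICRO	
96397-5	Microbiology - mycobacteriology studies			PANEL.MICRO	
96398-3	Microbiology - mycology studies			PANEL.MICRO	
92892-9	Microbiology - parasitic studies			PANEL.MICRO	
LA33214-0	2MRGN			LL	
LA33215-7	3MRGN			LL	
LA33216-5	4MRGN			LL	
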