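gene	cdna	protein	type	polyphen2	sift	mutation_taster	provean	maf	ada_score	rf_score	location	acmg
ANO5	c.242A>G	p.Asp81Gly	missense	probably damaging	deleterious			2.25e-04			11:22221158	PS4,PM3,PP3,PP4,PP5
ANO5	c.1203G>A	p.Trp401Ter	nonsense	stop gained	deleterious			0			11:22255393	PVS1,PM2,PM3,PP3,PP4
ANO5	c.2272C>T	p.Arg758Cys	missense	probably damaging	deleterious			3.30e-05			11:22274605	PS4,PM3,PP3,PP4,PP5
ANO5	c.69C>A	p.Tyr23Ter	nonsense	stop gained	deleterious			9.84e-06			11:22203832	PVS1,PM2,PM3,PP4
ANO5	c.1664G>T	p.Ser555Ile	missense	possibly damaging	deleterious			7.42e-05			11:22262162	PM3,PP3,PP4
ANO5	c.395A>T	p.Lys132Met	missense	probably damaging	deleterious			0			11:22227333	PM2,PM3,PP3,PP4
ANO5	c.2521C>G	p.His841Asp	missense	probably damaging	deleterious			1.67e-05	0.78	0.72	11:22279544	PM2,PM3,PP3,PP5,PP4
ANO5	c.191dupA	p.Asn64LysfsTer15	frameshift	frameshift	deleterious			1.03e-03			11:22221107	PVS1,PM3,PP4,PP5
ANO5	c.2012A>G	p.Tyr671Cys	missense	probably damaging	deleterious			8.24e-06			11:22270425	PM2,PM3,PP3,PP4
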