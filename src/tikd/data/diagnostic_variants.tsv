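gene	hgvs_c	hgvs_p	variant_type	chromosome_class	acmg_class	posterior	individual_id	categories	biopsy	anticipated_clinically
COL4A5	c.875G>A	p.(Gly292Glu)	SNV	gonosome	4	0.97	Ind_924166	gout	yes	yes
COL4A5	c.1871G>A	p.(Gly624Asp)	SNV	gonosome	5	1.00	Ind_734367	hereditary disorders	no	no
COL4A5	c.2023G>A	p.(Gly675Ser)	SNV	gonosome	4	0.90	Ind_408589	hereditary disorders	no	yes
COL4A5	c.1871G>A	p.(Gly624Asp)	SNV	gonosome	5	1.00	Ind_553814	hereditary disorders	yes	no
COL4A5	c.1871G>A	p.(Gly624Asp)	SNV	gonosome	5	1.00	Ind_674188	hereditary disorders	yes	no
COL4A5	c.1894G>A	p.(Gly632Ser)	SNV	gonosome	4	0.97	Ind_523397	hereditary disorders	yes	no
COL4A5	c.3196G>A	p.(Gly1066Ser)	SNV	gonosome	5	1.00	Ind_120641	hereditary disorders	yes	no
COL4A5	c.3275G>A	p.(Gly1092Glu)	SNV	gonosome	4	0.90	Ind_320658	hereditary disorders	yes	no
COL4A5	chrX:g.(?_107683936)_(107918029_?)del		CNV	gonosome	5		Ind_739404	hereditary disorders	yes	no
COL4A5	c.1871G>A	p.(Gly624Asp)	SNV	gonosome	5	1.00	Ind_276132	IgA nephropathy	yes	no
COL4A5	c.3508G>A	p.(Gly1170Ser)	SNV	gonosome	5	1.00	Ind_245000	IgA nephropathy;chronic glomerulonephritis	no	no
COL4A5	c.1871G>A	p.(Gly624Asp)	SNV	gonosome	5	1.00	Ind_768032	nephrosclerosis	yes	no
COL4A5	c.1871G>A	p.(Gly624Asp)	SNV	gonosome	5	1.00	Ind_197144	nephrosclerosis	yes	no
COL4A5	c.1871G>A	p.(Gly624Asp)	SNV	gonosome	5	1.00	Ind_905960	nephrosclerosis	yes	no
COL4A5	c.1871G>A	p.(Gly624Asp)	SNV	gonosome	5	1.00	Ind_540052	nephrosclerosis;gout	yes	no
COL4A5	c.1871G>A	p.(Gly624Asp)	SNV	gonosome	5	1.00	Ind_902111	unknown	no	no
COL4A4	c.5048G>A	p.(Cys1683Tyr)	SNV	autosome	4	0.90	Ind_330223	hereditary disorders	no	yes
COL4A4	c.2242G>A	p.(Gly748Ser)	SNV	autosome	4	0.90	Ind_203846	IgA nephropathy	yes	no
COL4A4	c.4832G>A	p.(Gly1611Glu)	SNV	autosome	4	0.90	Ind_641864	IgA nephropathy	yes	no
COL4A4	c.735G>A	p.[(=);0?]	SNV	autosome	4	0.90	Ind_251195	nephrosclerosis	yes	no
COL4A4	c.3707G>A	p.(Gly1236Glu)	SNV	autosome	4	0.90	Ind_591007	nephrosclerosis;interstitial nephritis	yes	no
COL4A4	c.93_94del	p.(Ser32Cysfs*28)	indel	autosome	5	1.00	Ind_805187	unknown	no	no
COL4A4	c.736G>A	p.(Gly246Ser)	SNV	autosome	4	0.97	Ind_218190	unknown	no	no
COL4A4	c.1935_1952del	p.(Pro647_Val652del)	indel	autosome	4	0.99	Ind_712115	unknown	no	no
COL4A3	c.688G>A	p.(Gly230Ser)	SNV	autosome	4	0.90	Ind_800358	gout	no	no
COL4A3	c.1595G>A	p.(Gly532Asp)	SNV	autosome	4	0.97	Ind_977173	gout;hereditary disorders	no	no
COL4A3	c.1559G>A	p.(Gly520Asp)	SNV	autosome	4	0.97	Ind_553814	hereditary disorders	yes	no
COL4A3	c.4388G>C	p.(Gly1463Ala)	SNV	autosome	4	0.90	Ind_458246	IgA nephropathy	yes	no
HNF1B	chr17:g.(?_34914860)_(36105069_?)dup		CNV	autosome	5		Ind_207310	nephrosclerosis	no	no
HNF1B	c.742C>G	p.(Gln248Glu)	SNV	autosome	4	0.90	Ind_197144	nephrosclerosis	yes	no
HNF1B	c.810-1G>A	p.0?	SNV	autosome	5	1.00	Ind_861194	others	no	no
HNF1B	chr17:g.(?_34475214)_(36504124_?)del		CNV	autosome	5		Ind_958149	unknown	no	no
UMOD	c.608G>A	p.(Cys203Tyr)	SNV	autosome	5	1.00	Ind_725568	interstitial nephritis	no	no
UMOD	c.673G>T	p.(Gly225Cys)	SNV	autosome	4	0.90	Ind_395543	interstitial nephritis	yes	no
UMOD	c.548G>A	p.(Cys183Tyr)	SNV	autosome	4	0.97	Ind_777983	nephrosclerosis;interstitial nephritis	no	no
MT-TF	chrM:g.616T>C		mito_SNV	mitochondrial	5	0.99	Ind_151715	unknown	no	no
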