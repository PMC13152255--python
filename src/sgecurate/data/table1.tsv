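variant_id	hgvs_p	n_patients	evidence	points	classification	sge_hap1	sge_mes	combined_lr	posterior	iarc_class
c.7436-4A>G	p.?	2	BP4; BP7_S (RNA)	-5	LBV	-4	2	1.493	0.435
c.7481G>T	p.(Arg2494Leu)	1	PM2_P; BP4	0	VUS	-4	4	0.684	0.745
c.7661G>T	p.(Ser2554Ile)	1	PM2_P	1	VUS	-4	2	1.030	0.296
c.7691C>G	p.(Thr2564Ser)	27	BS1_P; BS2_P; BP4	-3	LBV	-4	2	0.000	0.000	1
c.7768T>C	p.(Ser2590Pro)	1	PM2_P; BP4	0	VUS	0	-4	0.253	0.008	2
c.8156T>C	p.(Ile2719Thr)	1	BP4	-1	VUS	-4	0	0.684	0.218
c.8342A>G	p.(Asn2781Ser)	5	PM2_P; BP4	0	VUS	4	0	0.512	0.499
c.8499G>A	p.(Lys2833=)	1	BS1; BP4; BP7	-6	LBV	-4	0	0.253	0.005	2
c.8944A>C	p.(Lys2982Gln)	5	BS1_P; BP4	-2	LBV	4	-4	0.024	0.001	1
c.8991T>G	p.(Tyr2997*)	9	PVS1; PM2_P; PM5_S	13	PV	4	-4	29.348	0.999	5
c.9117+1G>A	p.?	1	PVS1 (RNA); PS1_P; PM2_P	10	PV	-2	4
c.9232G>T	p.(Val3078Phe)	1	PM2_P	1	VUS	4	0	0.778	0.023
c.9533A>C	p.(Asn3178Thr)	1	PM2_P; BP4	0	VUS	2	-4	1.030	0.031
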