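variant_id	hgvs_p	n_patients	evidence	sge_hap1	sge_mes	integrated_evidence	final_criteria	final_class
c.7805G>A	p.(Arg2602Lys)	1	PS1_M; PP3	4	4	PS3	PS1_M; PS3; PP3	LPV
c.8069T>A	p.(Val2690Asp)	1	PM2_P; PP3	4	4	PS3	PS3; PM2_P; PP3	LPV
c.9221T>C	p.(Leu3074Pro)	6	PM2_P; PP1_M; PP3	4	4	PS3	PS3; PM2_P; PP1_M; PP3	LPV
c.7523G>T	p.(Gly2508Val)	1	PM2_P	4	4	PS3	PS3; PM2_P	VUS
c.7871A>G	p.(Tyr2624Cys)	1	PP3	4	2	PS3	PS3; PP3	VUS
c.7469T>A	p.(Ile2490Lys)	1	PM2_P; BP4	-4	-4	BS3	PM2_P; BS3; BP4	LBV
c.7490A>C	p.(Lys2497Thr)	2	PM2_P; BP4	-4	-4	BS3	PM2_P; BS3; BP4	LBV
c.7590A>G	p.(Gln2530=)	1	PM2_P; BP4; BP7	-4	-4	BS3	PM2_P; BS3; BP4; BP7	LBV
c.7592T>C	p.(Val2531Ala)	1	PM2_P; BP4	-4	-4	BS3	PM2_P; BS3; BP4	LBV
c.7671A>C	p.(Ala2557=)	1	PM2_P; BP4; BP7	-4	-4	BS3	PM2_P; BS3; BP4; BP7	LBV
c.7735A>G	p.(Ile2579Val)	1	PM2_P; BP4	-4	-4	BS3	PM2_P; BS3; BP4	LBV
c.7814G>A	p.(Cys2605Tyr)	8		-2	-4	BS3	BS3	LBV
c.7901T>A	p.(Met2634Lys)	3	PP3	-4	-4	BS3	PP3; BS3	LBV
c.8047G>C	p.(Ala2683Pro)	1	PM2_P; PP3	-4	-4	BS3	PM2_P; PP3; BS3	LBV
c.8215G>C	p.(Val2739Leu)	1	BP4	-4	-4	BS3	BS3; BP4	LBV
c.8428A>C	p.(Ser2810Arg)	1	PM2_P; BP4	-4	-4	BS3	PM2_P; BS3; BP4	LBV
c.8488-3C>A	p.?	1	PM2_P; PP3	-4	-4	BS3	PM2_P; PP3; BS3	LBV
c.8587G>A	p.(Glu2863Lys)	1	PM2_P; PP3	-4	-4	BS3	PM2_P; PP3; BS3	LBV
c.8744C>T	p.(Ala2915Val)	1	PM2_P; BP4	-4	-4	BS3	PM2_P; BS3; BP4	LBV
c.8914T>C	p.(Leu2972=)	1	PM2_P; BP4; BP7	-4	-4	BS3	PM2_P; BS3; BP4; BP7	LBV
c.8968T>C	p.(Trp2990Arg)	1	PM2_P	-4	-4	BS3	PM2_P; BS3	LBV
c.9100C>G	p.(Gln3034Glu)	1	PM2_P; BP4	-4	-4	BS3	PM2_P; BS3; BP4	LBV
c.9111A>G	p.(Gln3037=)	1	PM2_P; BP4; BP7	-4	-4	BS3	PM2_P; BS3; BP4; BP7	LBV
c.9161C>G	p.(Pro3054Arg)	1	PM2_P; BP4	-4	-4	BS3	PM2_P; BS3; BP4	LBV
c.9166C>T	p.(His3056Tyr)	1	BP4	-4	-4	BS3	BS3; BP4	LBV
c.9309A>G	p.(Ile3103Met)	1	PM2_P; BP4	-4	-4	BS3	PM2_P; BS3; BP4	LBV
c.9403C>G	p.(Leu3135Val)	3	PM2_P; BP4	-4	-4	BS3	PM2_P; BS3; BP4	LBV
c.9485T>G	p.(Met3162Arg)	1	PM2_P	-4	-4	BS3	PM2_P; BS3	LBV
c.9544C>T	p.(His3182Tyr)	2	PM2_P; BP4	-4	-4	BS3	PM2_P; BS3; BP4	LBV
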