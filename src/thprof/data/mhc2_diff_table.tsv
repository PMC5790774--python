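gene	gene_id	gata3_ko	bcl6_ko	hdac6_ko
Cd74	16149	1.33	5.16	
Ciita	12265			-1.24
H2-Aa	14960	1.45	1.99	-1.28
H2-Ab1	14961	1.42	2.39	
H2-DMa	14998	1.45		-1.38
H2-DMb1	14999			
H2-DMb2	15000	1.22		-1.34
H2-Ea-ps	100504404			
H2-Eb1	14969	1.41	1.47	-1.23
H2-Eb2	381091			
H2-K1	14972		1.6	
H2-Oa	15001	1.48		
H2-Ob	15002		-1.66	
Mr1	15064			
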