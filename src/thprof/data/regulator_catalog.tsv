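symbol	common_name	unigene_human	unigene_mouse	category	subsets
AHR	Aryl hydrocarbon receptor	Hs.171189	Mm.341377	transcription_factor	Th22
ACT1	Act1	N/A	N/A	transcription_factor	Th25
BATF	BATF	Hs.509964	Mm.6672	transcription_factor	Tfh
BACH2	BACH2	Hs.269764	Mm.491223	transcription_factor	Treg
BCL6	BCL6	Hs.478588	Mm.347398	transcription_factor	Tfh
CMIP	c-MAF	Hs.594095	Mm.233181	transcription_factor	Th2
EOMES	EOMES	Hs.591663	Mm.200692	transcription_factor	Th1
FOXO1	FOXO1	Hs.370666	Mm.29891	transcription_factor	Treg
FOXO3	FOXO3	Hs.220950	Mm.338613	transcription_factor	Treg
FOXP3	Foxp3	Hs.247700	Mm.182291	transcription_factor	Treg
GATA3	Gata-3	Hs.524134	Mm.313866	transcription_factor	Th2
HNF1A	TCF1	Hs.654455	Mm.332607	transcription_factor	Tfh,Th17
IRF4	IRF4	Hs.401013	Mm.4677	transcription_factor	Th2,Th9,Tfh
IKZF4	IKZF4	Hs.553221	Mm.358648	transcription_factor	Treg
MAF	MAF	Hs.134859	Mm.439772	transcription_factor	Tfh
RORC	RORgammaT	Hs.256022	Mm.4372	transcription_factor	Th17
RORA	RORalpha	Hs.560343/Hs.655155	Mm.427266	transcription_factor	Th17
RUNX3	RUNX3	Hs.170019	Mm.378894	transcription_factor	Th1
SPI1	PU.1	Hs.502511	Mm.1302	transcription_factor	Th9
TBX21	T-bet	Hs.272409	Mm.94519	transcription_factor	Th1
STAT1	STAT1	Hs.743244	Mm.277406	transcription_activator	Th1
STAT3	STAT3	Hs.463059	Mm.249934	transcription_activator	Tfh
STAT4	STAT4	Hs.80642	Mm.1550	transcription_activator	Th1
STAT5A	STAT5	Hs.437058	N/A	transcription_activator	Treg
STAT6	STAT6	Hs.524518	Mm.121721	transcription_activator	Th9
GFI1	GFI1	Hs.73172	Mm.2078/Mm.453139	transcription_repressor	Th2
SMAD2	SMAD2	Hs.12253	Mm.152699	signal_transducer	Th9,Treg
SMAD3	SMAD3	Hs.727986	Mm.7320	signal_transducer	Th9,Treg
CCL15	CCL15	Hs.272493	N/A	cytokine	Th22
CCL17	CCL17	Hs.546294	Mm.41988	cytokine	Th22
IL2	IL-2	Hs.89679	Mm.14190	cytokine	Th1,Th2,Th9,Treg
IL4	IL-4	Hs.73917	Mm.276360	cytokine	Th2,Th9
IL5	IL-5	Hs.2247	Mm.4461	cytokine	Th2,Th9
IL6	IL-6	Hs.654458	Mm.1019	cytokine	Tfh,Th17
IL9	IL-9	Hs.960	Mm.3006	cytokine	Th9
IL10	IL-10	Hs.193717	Mm.874	cytokine	Treg
IL12RB1	IL-12	Hs.567294	N/A	cytokine	Th1
IL13	IL-13	Hs.845	Mm.1284	cytokine	Th2
IL17B	IL-17	Hs.156979	N/A	cytokine	Th17
IL17F	IL-17F	Hs.272295	Mm.222807	cytokine	Th17
IL21	IL-21	Hs.567559	Mm.157689	cytokine	Tfh,Th17
IL22	IL-22	Hs.287369	Mm.103585	cytokine	Th17
IL23	IL-23	N/A	N/A	cytokine	Th17
IL25	IL-25	Hs.302036	Mm.90154	cytokine	Th25
IL27	IL-27	Hs.528111	Mm.222632	cytokine	Th1
IL10RB	IL10Rbeta	Hs.654593	Mm.4154	cytokine	Th22
ICOS	ICOS	Hs.56247	Mm.42044	cytokine	Tfh
IFNG	IFNgamma	Hs.856	Mm.240327	cytokine	Th1
CXCR5	CXCR5	Hs.113916	Mm.6246	lineage_factor	Tfh
IDO1	Indoleamine 2,3-dioxygenase 1	Hs.840	Mm.392	lineage_factor	Th2
MYD88	MyD88	Hs.82116	Mm.213003	lineage_factor	Th17
MTOR	mTOR	Hs.338207	Mm.21158	lineage_factor	Treg
TGIF1	TGFbeta	Hs.373550	Mm.101034	lineage_factor	Th9,Th17,Treg
RARA	RARA	Hs.654583	Mm.439744	receptor	Th1
CCR3	CCR3	Hs.506190	Mm.57050	receptor	Th9
CCR4	CCR4	Hs.184926	Mm.1337	receptor	Th2
CXCR3	CXCR3	Hs.198252	Mm.12876	receptor	Th1,Th9
CCR6	CCR6	Hs.46468	Mm.8007	receptor	Th17
CCR8	CCR8	Hs.113222	Mm.442098	receptor	Th2
CD28	CD28	Hs.443123	Mm.255003	other	Treg
CTLA4	CTLA4	Hs.247824	Mm.390	other	Treg
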