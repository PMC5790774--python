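gene	Adipose tissue	Adrenal gland	Bladder	Blood	Bone	Bone marrow	Brain	Cervix	Embryonic tissue	Esophagus	Eye	Heart	Intestine	Kidney	Liver	Lung	Lymph node	Mammary gland	Muscle	Nerve	Ovary	Pancreas	Placenta	Prostate	Skin	Spleen	Stomach	Thymus	Trachea	Umbilical cord	Uterus	Vascular
AHR	+	-	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	++	++	-	+	++	+	+	-	+	+	+	+	+	+
BATF	-	-	-	+	-	-	-	-	-	-	-	-	+	-	-	+	++	+	-	-	-	-	-	+	+	-	+	-	-	-	+	+
BACH2	-	-	-	++	-	-	++	-	+	-	+	-	-	-	-	+	++	+	++	-	-	++	-	+	-	-	-	+	-	-	-	-
BCL6	++	+	+	+	+	-	+	+	-	-	+	+	+	+	+	+	+	+	+	++	+	+	+	+	+	+	+	+	++	-	+	+
CMIP	+	+	++	+	++	-	+	-	+	-	++	+	+	+	+	++	+	+	+	++	+	+	+	+	+	+	+	+	++	-	+	+
EOMES	-	-	-	-	-	-	+	-	+	-	+	-	-	-	-	+	-	+	-	-	-	-	-	-	-	-	-	-	-	-	+	-
FOXO1	-	-	-	+	+	+	+	+	+	-	+	+	+	+	+	+	++	+	+	+	++	+	+	+	+	-	+	+	+	-	+	+
FOXO3	+	+	-	+	+	-	+	+	+	+	++	+	+	+	+	+	+	+	++	+	+	+	+	+	+	+	+	+	+	+	+	+
FOXP3	-	-	-	+	-	-	-	-	-	-	+	-	-	-	-	+	+	+	-	-	-	-	-	-	-	+	-	+	++	-	-	-
GATA3	-	+	++	+	-	-	+	+	+	-	+	+	-	+	+	+	+	++	-	+	-	-	++	+	+	-	+	+	-	-	+	+
HNF1A	-	-	-	-	-	-	-	-	-	-	+	-	+	+	++	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-
IRF4	-	-	-	++	-	-	+	-	-	-	+	+	+	+	-	+	++	-	-	+	-	-	+	+	++	+	++	+	-	-	+	-
IKZF4	-	-	-	+	+	-	+	-	+	-	++	+	+	+	+	+	+	+	+	-	+	+	+	-	+	-	-	+	-	-	+	-
MAF	+	+	-	+	+	-	+	+	+	-	+	+	+	++	+	+	+	+	++	++	+	+	+	+	+	+	+	-	-	-	+	+
RORC	-	+	++	-	+	-	+	++	-	-	-	-	+	+	++	+	++	+	++	-	-	+	-	+	-	-	+	++	++	-	+	-
RORA	-	++	-	-	+	-	+	-	-	-	++	-	+	++	++	+	-	++	++	-	+	++	++	+	++	-	+	+	++	-	+	+
RUNX3	+	-	-	+	+	+	+	+	+	-	+	++	+	+	-	+	++	+	-	-	-	+	+	+	+	++	+	+	++	-	+	-
SPI1	-	-	-	++	-	-	+	-	-	-	+	++	++	++	++	++	++	+	-	-	++	-	++	+	-	++	+	++	-	-	-	-
TBX21	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	+	-	-	-	++	-	-	-	-	-	-
STAT1	+	+	+	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	++	-	+	+
STAT3	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	++	+	+	+	+	+	+	+	+	++	-	+	+
STAT4	-	-	-	++	-	++	+	-	+	-	+	++	+	+	-	+	+	+	++	-	+	-	++	-	+	++	-	++	-	-	+	-
STAT5A	+	-	+	+	+	-	+	+	+	-	+	+	+	+	+	+	++	+	+	-	+	+	+	+	+	+	+	+	++	-	+	+
STAT6	-	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	++	+	+	+
GFI1	-	-	-	+	-	++	-	-	-	-	-	-	+	-	-	+	+	-	-	-	-	+	-	-	-	+	-	+	-	-	+	-
SMAD2	+	+	+	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	++	+	+	+	+	+	+	+	+	-	-	+	+
SMAD3	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	++	-	+	+	+	+	+	+	+	+	+	-	+	+
CCL15	-	-	-	-	-	-	+	-	-	-	-	-	+	++	+	+	-	-	-	-	-	-	-	+	-	-	-	-	++	-	+	-
CCL17	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-
IL2	-	-	-	++	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
IL4	-	-	-	++	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	++	-	-	-	-	-	-
IL5	-	-	-	+	++	-	+	-	-	-	++	-	+	++	-	++	+	-	++	-	+	++	+	-	++	+	-	+	-	-	-	++
IL6	+	+	+	+	+	+	+	+	+	-	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	++	+	+	+
IL9	-	-	-	-	-	-	-	-	-	-	-	-	-	++	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
IL10	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
IL12RB1	++	-	-	+	+	+	+	-	-	-	-	-	+	+	+	+	+	-	-	-	-	-	+	-	+	++	+	+	-	-	-	-
IL13	-	-	-	-	-	++	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
IL17B	-	-	-	-	++	-	-	-	-	-	+	++	-	-	-	+	-	-	-	-	-	-	+	+	-	-	-	-	-	-	-	-
IL17F	-	-	-	++	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
IL22	-	-	-	++	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
IL27	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	++	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
IL10RB	-	+	-	+	-	+	+	-	+	+	++	++	-	-	+	+	+	+	++	+	+	+	+	+	-	-	-	-	++	+	+	+
ICOS	-	-	-	+	-	-	-	-	-	-	-	++	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	+	-	-	+	-
IFNG	-	-	-	++	-	-	-	-	-	-	-	-	-	+	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
CXCR5	-	-	-	++	-	-	-	-	-	+	-	-	+	-	-	+	++	-	+	-	-	-	-	+	+	++	-	+	-	-	-	-
IDO1	-	-	-	-	+	-	-	-	+	-	+	+	+	+	+	+	-	+	+	-	+	+	++	-	-	-	+	-	-	-	+	-
MYD88	-	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	++	+	+	+
MTOR	+	-	-	+	+	+	+	+	+	+	+	+	+	+	+	+	++	+	++	-	+	+	+	+	+	+	-	+	++	-	+	+
TGIF1	+	-	+	+	+	-	+	+	+	-	+	+	+	+	+	+	+	+	++	-	+	+	+	+	+	+	+	+	-	-	+	-
RARA	-	+	-	+	+	+	+	+	+	+	+	+	+	+	+	+	+	++	+	+	+	+	+	+	+	+	+	+	++	-	+	+
CCR3	-	-	-	++	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-
CCR4	++	-	-	+	-	-	-	-	-	-	-	-	-	-	-	+	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-
CXCR3	-	-	-	+	-	-	-	-	-	-	-	-	+	-	-	-	-	-	++	-	-	-	-	-	-	+	-	-	-	-	-	-
CCR6	-	-	-	+	-	+	-	-	-	-	-	-	+	-	-	-	+	+	-	-	-	-	-	+	-	+	+	+	-	-	-	-
CCR8	-	-	-	++	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
CTLA4	-	-	-	+	-	-	-	-	-	-	-	-	-	+	-	+	++	+	-	-	-	-	-	+	-	-	-	-	-	-	-	-
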