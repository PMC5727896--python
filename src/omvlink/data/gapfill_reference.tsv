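bigg_id	name	reaction	reaction_type	reversibility	curated_override	producible	consumable	enzyme	mouse_gene
13zdst	Erucic acid	13zdstt-_rev_e	exporter	R	0	P	C
1ag	1-Acylglycerol	R07293	metabolic	R	0	P	C	Monoacylglycerol acylhydrolase	Lipe (16890.1)
3amp	Adenosine 3'-phosphate	R01562	metabolic	I	0	NP	C	3'-AMP phosphohydrolase (3.1.3.6)
3amp	Adenosine 3'-phosphate	R03537	metabolic	I	0	P	NC	2',3'-Cyclic AMP 3'-nucleotidohydrolase (3.1.4.16)
3c3hmp	Alpha-Isopropylmalate	R01213	metabolic	I	0	P	NC	Acetyl-CoA:3-methyl-2-oxobutanoate C-acetyltransferase (2.3.3.13)
9z12zocdcya	Linoleate	R08177	metabolic	I	0	NP	C	Linoleoyl-CoA hydrolase (3.1.2.2)	Acot2 (171210.1)
achms	O-Acetyl-homoserine	R01287	metabolic	I	0	NP	C	O-Acetyl-L-homoserine acetate-lyase (2.5.1.49)
achms	O-Acetyl-homoserine	R01776	metabolic	I	0	P	NC	Acetyl-CoA:L-homoserine O-acetyltransferase (2.3.1.31)
crtn	Creatinine	R01884	metabolic	R	0	P	C	Creatinine amidohydrolase (3.5.2.10)
g3pe	Glycerophosphoethanolamine	R01470	metabolic	I	0	NP	C	Glycerophosphohydrolase (3.1.4.2)	Gpcpd1 (74182.1)
genistein	Genistein	R06553	metabolic	I	1	NP	C	Isoflavone synthase
hom__L	L-Homoserine	R01776	metabolic	I	0	NP	C	Acetyl-CoA:L-homoserine O-acetyltransferase (2.3.1.31)
hom__L	L-Homoserine	R00175	metabolic	I	1	P	NC	S-Adenosyl-L-methionine hydrolase (3.3.1.2)
idt__L	L-Iditol	R07145	metabolic	R	0	P	C	L-Iditol:NAD+ 2-oxidoreductase	Sord (20322.1)
malon	Malonate	R00743	metabolic	R	0	P	C	Acetyl-CoA:malonate CoA-transferase (2.8.3.3)
maltttr	Maltotetraose	R03801	metabolic	I	0	NP	C	1,4-Beta-D-Glucan glucohydrolase (3.2.1.74)
maltttr	Maltotetraose	R03802	metabolic	I	0	P	NC	1,4-Beta-D-Glucan glucohydrolase (3.2.1.74)
metsox_S__L	L-Methionine S-oxide	R02025	metabolic	I	0	NP	C	L-Methionine:oxidized-thioredoxin S-oxidoreductase	Msrb2 and Msrb3 (76467.1 and 320183.1)
psphings	Phytosphingosine	R06525	metabolic	I	0	P	NC	Sphinganine, ferrocytochrome b5:oxygen oxidoreductase	Degs2 (70059.1)
rbn__D	D-Ribonate	R01079	metabolic	R	1	P	C	D-Ribose:NADP+ 1-oxidoreductase (1.1.1.115)
saccrp__L	Saccharopine	R00715	metabolic	R	0	P	C	N6-(L-1,3-dicarboxypropyl)-L-lysine:NAD+ oxidoreductase (1.5.1.7)
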