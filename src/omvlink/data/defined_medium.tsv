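compound	concentration	unit
KH2PO4	100	mM
NaCl	15	mM
(NH4)2SO4	8.5	mM
MgCl2	0.1	mM
L-Cysteine	4.1	mM
Vitamin B12	3.7e-7	mM
Hematin	0.0015	mM
Glucose	0.5	% w/v
CaCl2	0.05	mM
Histidine	0.2	mM
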