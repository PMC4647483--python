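gene	description	value
RNY1	RNA, Ro-associated Y1	847620
RNY4	RNA, Ro-associated Y4	215019
RPPH1	ribonuclease P RNA component H1	96625
RN7SK	RNA, 7SK small nuclear	41008
UBA52	Ubiquitin A-52 residue ribosomal protein fusion product 1	15576
UBB	Ubiquitin B	15389
BNIP3L	BCL2/adenovirus E1B 19 kDa interacting protein 3-like	14362
SLC25A37	Solute carrier family 25 (mitochondrial iron transporter), member 37	12246
FTL	ferritin, light polypeptide	10475
SNCA	synuclein, alpha (non A4 component of amyloid precursor)	9959
TMEM56	transmembrane protein 56	8918
RPS12	ribosomal protein S12	7359
EPB41	erythrocyte membrane protein band 4.1 (elliptocytosis 1, RH-linked)	6337
GYPC	glycophorin C (Gerbich blood group)	5744
RN7SL4P	RNA, 7SL, cytoplasmic 4, pseudogene	4953
AC079949.1	no description available	4543
PICALM	Phosphatidylinositol binding clathrin assembly protein	4443
OAZ1	Ornithine decarboxylase antizyme 1	4330
ALAS2	5,-aminolevulinate synthase 2	4289
MBOAT2	Membrane bound O-acyltransferase domain containing 2	4250
RNY5	RNA, Ro-associated Y5	4027
FBXO7	F-box protein 7	4008
DNAJC6	DnaJ (Hsp40) homolog, subfamily C, member 6	3660
ADIPOR1	Adiponectin receptor 1	3574
SERF2	small EDRK-rich factor 2	3398
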