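# Carbon precursor map for the 20 standard amino acids in E. coli grown on
# glucose minimal medium.
#
# Each row assigns one carbon site of a residue type to a precursor molecule.
# Carbons sharing a molecule id within one residue derive from the SAME
# precursor molecule and are co-labeled when that molecule comes from a single
# glucose; carbons on different molecule ids are labeled independently.
# precursor_carbon is the carbon index within the precursor; a covalent bond
# of the residue is "intact" when both carbons share a molecule id and have
# consecutive precursor_carbon indices.
#
# family tags: pyruvate, PEP/E4P, pentose-phosphate, oxaloacetate,
# 2-oxoglutarate, 3-phosphoglycerate, acetyl-CoA, one-carbon.
# oxaloacetate and 2-oxoglutarate molecules are subject to TCA bond
# scrambling; one-carbon units (C1/THF, carbamoyl-P, purine C2) carry a
# single carbon and have no internal bonds.
#
# Sources of the mapping, per residue:
#   Ala, Val, Leu, Ile  pyruvate / acetolactate chemistry incl. the methyl
#                       migration that splits the two pyruvates across the
#                       diastereotopic methyls (pro-R methyl stays bonded to
#                       its precursor neighbor, pro-S does not)
#   Phe, Tyr, Trp ring  shikimate: PEP + erythrose-4-phosphate
#   His                 PRPP ribose C1-C5 plus purine C2 for CE1
#   Ser, Gly, Cys, Trp  3-phosphoglycerate backbone
#   Asp, Asn, Thr, Met, Lys(CG-CE)  oxaloacetate / aspartate family
#   Glu, Gln, Pro, Arg  2-oxoglutarate
#   Lys(C,CA,CB)        pyruvate half of diaminopimelate
#   Leu(C,CA)           acetyl-CoA
#
# residue	atom	molecule	precursor_carbon	family
ALA	C	p1	1	pyruvate
ALA	CA	p1	2	pyruvate
ALA	CB	p1	3	pyruvate
ARG	C	k1	1	2-oxoglutarate
ARG	CA	k1	2	2-oxoglutarate
ARG	CB	k1	3	2-oxoglutarate
ARG	CG	k1	4	2-oxoglutarate
ARG	CD	k1	5	2-oxoglutarate
ARG	CZ	c1	1	one-carbon
ASN	C	o1	1	oxaloacetate
ASN	CA	o1	2	oxaloacetate
ASN	CB	o1	3	oxaloacetate
ASN	CG	o1	4	oxaloacetate
ASP	C	o1	1	oxaloacetate
ASP	CA	o1	2	oxaloacetate
ASP	CB	o1	3	oxaloacetate
ASP	CG	o1	4	oxaloacetate
CYS	C	s1	1	3-phosphoglycerate
CYS	CA	s1	2	3-phosphoglycerate
CYS	CB	s1	3	3-phosphoglycerate
GLN	C	k1	1	2-oxoglutarate
GLN	CA	k1	2	2-oxoglutarate
GLN	CB	k1	3	2-oxoglutarate
GLN	CG	k1	4	2-oxoglutarate
GLN	CD	k1	5	2-oxoglutarate
GLU	C	k1	1	2-oxoglutarate
GLU	CA	k1	2	2-oxoglutarate
GLU	CB	k1	3	2-oxoglutarate
GLU	CG	k1	4	2-oxoglutarate
GLU	CD	k1	5	2-oxoglutarate
GLY	C	s1	1	3-phosphoglycerate
GLY	CA	s1	2	3-phosphoglycerate
HIS	CD2	r1	1	pentose-phosphate
HIS	CG	r1	2	pentose-phosphate
HIS	CB	r1	3	pentose-phosphate
HIS	CA	r1	4	pentose-phosphate
HIS	C	r1	5	pentose-phosphate
HIS	CE1	f1	1	one-carbon
ILE	C	o1	1	oxaloacetate
ILE	CA	o1	2	oxaloacetate
ILE	CG1	o1	3	oxaloacetate
ILE	CD1	o1	4	oxaloacetate
ILE	CB	p1	2	pyruvate
ILE	CG2	p1	3	pyruvate
LEU	C	a1	1	acetyl-CoA
LEU	CA	a1	2	acetyl-CoA
LEU	CB	p1	2	pyruvate
LEU	CD2	p1	3	pyruvate
LEU	CG	p2	2	pyruvate
LEU	CD1	p2	3	pyruvate
LYS	C	p1	1	pyruvate
LYS	CA	p1	2	pyruvate
LYS	CB	p1	3	pyruvate
LYS	CG	o1	4	oxaloacetate
LYS	CD	o1	3	oxaloacetate
LYS	CE	o1	2	oxaloacetate
MET	C	o1	1	oxaloacetate
MET	CA	o1	2	oxaloacetate
MET	CB	o1	3	oxaloacetate
MET	CG	o1	4	oxaloacetate
MET	CE	m1	1	one-carbon
PHE	C	e1	1	PEP/E4P
PHE	CA	e1	2	PEP/E4P
PHE	CB	e1	3	PEP/E4P
PHE	CG	e2	2	PEP/E4P
PHE	CD1	e2	3	PEP/E4P
PHE	CD2	r1	1	PEP/E4P
PHE	CE2	r1	2	PEP/E4P
PHE	CZ	r1	3	PEP/E4P
PHE	CE1	r1	4	PEP/E4P
PRO	C	k1	1	2-oxoglutarate
PRO	CA	k1	2	2-oxoglutarate
PRO	CB	k1	3	2-oxoglutarate
PRO	CG	k1	4	2-oxoglutarate
PRO	CD	k1	5	2-oxoglutarate
SER	C	s1	1	3-phosphoglycerate
SER	CA	s1	2	3-phosphoglycerate
SER	CB	s1	3	3-phosphoglycerate
THR	C	o1	1	oxaloacetate
THR	CA	o1	2	oxaloacetate
THR	CB	o1	3	oxaloacetate
THR	CG2	o1	4	oxaloacetate
TRP	C	s1	1	3-phosphoglycerate
TRP	CA	s1	2	3-phosphoglycerate
TRP	CB	s1	3	3-phosphoglycerate
TRP	CG	r1	1	pentose-phosphate
TRP	CD1	r1	2	pentose-phosphate
TRP	CD2	e1	2	PEP/E4P
TRP	CE2	e1	3	PEP/E4P
TRP	CE3	w1	1	PEP/E4P
TRP	CZ3	w1	2	PEP/E4P
TRP	CH2	w1	3	PEP/E4P
TRP	CZ2	w1	4	PEP/E4P
TYR	C	e1	1	PEP/E4P
TYR	CA	e1	2	PEP/E4P
TYR	CB	e1	3	PEP/E4P
TYR	CG	e2	2	PEP/E4P
TYR	CD1	e2	3	PEP/E4P
TYR	CD2	r1	1	PEP/E4P
TYR	CE2	r1	2	PEP/E4P
TYR	CZ	r1	3	PEP/E4P
TYR	CE1	r1	4	PEP/E4P
VAL	C	p1	1	pyruvate
VAL	CA	p1	2	pyruvate
VAL	CG2	p1	3	pyruvate
VAL	CB	p2	2	pyruvate
VAL	CG1	p2	3	pyruvate
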