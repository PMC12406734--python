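# Chemistry roles per residue template (side chains + backbone amide/carbonyl).
# role = donor: `partner` lists the covalent hydrogens of the donor heavy atom.
# role = acceptor: `partner` is the acceptor antecedent (AA), the heavy atom
#                  bonded to the acceptor, used in the H-A-AA / D-A-AA angles.
# role = acidic_o / basic_n: side-chain charged-group membership for salt
#                  bridges (Asp/Glu carboxylate oxygens; Lys amine / Arg
#                  guanidinium nitrogens). Histidine is intentionally absent
#                  from basic_n (protonation-state dependent; opt in via
#                  ChemistryRoles.default(include_histidine_basic=True)).
residue	atom	role	partner
ALA	N	donor	H
ALA	O	acceptor	C
ARG	N	donor	H
ARG	O	acceptor	C
ARG	NE	donor	HE
ARG	NH1	donor	HH11,HH12
ARG	NH2	donor	HH21,HH22
ARG	NE	basic_n	-
ARG	NH1	basic_n	-
ARG	NH2	basic_n	-
ASN	N	donor	H
ASN	O	acceptor	C
ASN	OD1	acceptor	CG
ASN	ND2	donor	HD21,HD22
ASP	N	donor	H
ASP	O	acceptor	C
ASP	OD1	acceptor	CG
ASP	OD2	acceptor	CG
ASP	OD1	acidic_o	-
ASP	OD2	acidic_o	-
CYS	N	donor	H
CYS	O	acceptor	C
CYS	SG	donor	HG
GLN	N	donor	H
GLN	O	acceptor	C
GLN	OE1	acceptor	CD
GLN	NE2	donor	HE21,HE22
GLU	N	donor	H
GLU	O	acceptor	C
GLU	OE1	acceptor	CD
GLU	OE2	acceptor	CD
GLU	OE1	acidic_o	-
GLU	OE2	acidic_o	-
GLY	N	donor	H
GLY	O	acceptor	C
HIS	N	donor	H
HIS	O	acceptor	C
HIS	ND1	donor	HD1
HIS	NE2	acceptor	CE1
ILE	N	donor	H
ILE	O	acceptor	C
LEU	N	donor	H
LEU	O	acceptor	C
LYS	N	donor	H
LYS	O	acceptor	C
LYS	NZ	donor	HZ1,HZ2,HZ3
LYS	NZ	basic_n	-
MET	N	donor	H
MET	O	acceptor	C
PHE	N	donor	H
PHE	O	acceptor	C
PRO	O	acceptor	C
SER	N	donor	H
SER	O	acceptor	C
SER	OG	donor	HG
SER	OG	acceptor	CB
THR	N	donor	H
THR	O	acceptor	C
THR	OG1	donor	HG1
THR	OG1	acceptor	CB
TRP	N	donor	H
TRP	O	acceptor	C
TRP	NE1	donor	HE1
TYR	N	donor	H
TYR	O	acceptor	C
TYR	OH	donor	HH
TYR	OH	acceptor	CZ
VAL	N	donor	H
VAL	O	acceptor	C
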