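# Per-residue atom templates for the 20 standard amino acids.
# Heavy atoms plus polar hydrogens (CHARMM-style names). `parent` is the atom
# each entry is covalently bonded to inside the residue; the backbone N of
# residue i+1 bonds to C of residue i (added by the topology builder, not
# listed here). Atom order here is the canonical file order.
residue	atom	element	parent
ALA	N	N	-
ALA	H	H	N
ALA	CA	C	N
ALA	C	C	CA
ALA	O	O	C
ALA	CB	C	CA
ARG	N	N	-
ARG	H	H	N
ARG	CA	C	N
ARG	C	C	CA
ARG	O	O	C
ARG	CB	C	CA
ARG	CG	C	CB
ARG	CD	C	CG
ARG	NE	N	CD
ARG	HE	H	NE
ARG	CZ	C	NE
ARG	NH1	N	CZ
ARG	HH11	H	NH1
ARG	HH12	H	NH1
ARG	NH2	N	CZ
ARG	HH21	H	NH2
ARG	HH22	H	NH2
ASN	N	N	-
ASN	H	H	N
ASN	CA	C	N
ASN	C	C	CA
ASN	O	O	C
ASN	CB	C	CA
ASN	CG	C	CB
ASN	OD1	O	CG
ASN	ND2	N	CG
ASN	HD21	H	ND2
ASN	HD22	H	ND2
ASP	N	N	-
ASP	H	H	N
ASP	CA	C	N
ASP	C	C	CA
ASP	O	O	C
ASP	CB	C	CA
ASP	CG	C	CB
ASP	OD1	O	CG
ASP	OD2	O	CG
CYS	N	N	-
CYS	H	H	N
CYS	CA	C	N
CYS	C	C	CA
CYS	O	O	C
CYS	CB	C	CA
CYS	SG	S	CB
CYS	HG	H	SG
GLN	N	N	-
GLN	H	H	N
GLN	CA	C	N
GLN	C	C	CA
GLN	O	O	C
GLN	CB	C	CA
GLN	CG	C	CB
GLN	CD	C	CG
GLN	OE1	O	CD
GLN	NE2	N	CD
GLN	HE21	H	NE2
GLN	HE22	H	NE2
GLU	N	N	-
GLU	H	H	N
GLU	CA	C	N
GLU	C	C	CA
GLU	O	O	C
GLU	CB	C	CA
GLU	CG	C	CB
GLU	CD	C	CG
GLU	OE1	O	CD
GLU	OE2	O	CD
GLY	N	N	-
GLY	H	H	N
GLY	CA	C	N
GLY	C	C	CA
GLY	O	O	C
HIS	N	N	-
HIS	H	H	N
HIS	CA	C	N
HIS	C	C	CA
HIS	O	O	C
HIS	CB	C	CA
HIS	CG	C	CB
HIS	ND1	N	CG
HIS	HD1	H	ND1
HIS	CD2	C	CG
HIS	CE1	C	ND1
HIS	NE2	N	CE1
ILE	N	N	-
ILE	H	H	N
ILE	CA	C	N
ILE	C	C	CA
ILE	O	O	C
ILE	CB	C	CA
ILE	CG1	C	CB
ILE	CG2	C	CB
ILE	CD1	C	CG1
LEU	N	N	-
LEU	H	H	N
LEU	CA	C	N
LEU	C	C	CA
LEU	O	O	C
LEU	CB	C	CA
LEU	CG	C	CB
LEU	CD1	C	CG
LEU	CD2	C	CG
LYS	N	N	-
LYS	H	H	N
LYS	CA	C	N
LYS	C	C	CA
LYS	O	O	C
LYS	CB	C	CA
LYS	CG	C	CB
LYS	CD	C	CG
LYS	CE	C	CD
LYS	NZ	N	CE
LYS	HZ1	H	NZ
LYS	HZ2	H	NZ
LYS	HZ3	H	NZ
MET	N	N	-
MET	H	H	N
MET	CA	C	N
MET	C	C	CA
MET	O	O	C
MET	CB	C	CA
MET	CG	C	CB
MET	SD	S	CG
MET	CE	C	SD
PHE	N	N	-
PHE	H	H	N
PHE	CA	C	N
PHE	C	C	CA
PHE	O	O	C
PHE	CB	C	CA
PHE	CG	C	CB
PHE	CD1	C	CG
PHE	CD2	C	CG
PHE	CE1	C	CD1
PHE	CE2	C	CD2
PHE	CZ	C	CE1
PRO	N	N	-
PRO	CA	C	N
PRO	C	C	CA
PRO	O	O	C
PRO	CB	C	CA
PRO	CG	C	CB
PRO	CD	C	CG
SER	N	N	-
SER	H	H	N
SER	CA	C	N
SER	C	C	CA
SER	O	O	C
SER	CB	C	CA
SER	OG	O	CB
SER	HG	H	OG
THR	N	N	-
THR	H	H	N
THR	CA	C	N
THR	C	C	CA
THR	O	O	C
THR	CB	C	CA
THR	OG1	O	CB
THR	HG1	H	OG1
THR	CG2	C	CB
TRP	N	N	-
TRP	H	H	N
TRP	CA	C	N
TRP	C	C	CA
TRP	O	O	C
TRP	CB	C	CA
TRP	CG	C	CB
TRP	CD1	C	CG
TRP	CD2	C	CG
TRP	NE1	N	CD1
TRP	HE1	H	NE1
TRP	CE2	C	CD2
TRP	CE3	C	CD2
TRP	CZ2	C	CE2
TRP	CZ3	C	CE3
TRP	CH2	C	CZ2
TYR	N	N	-
TYR	H	H	N
TYR	CA	C	N
TYR	C	C	CA
TYR	O	O	C
TYR	CB	C	CA
TYR	CG	C	CB
TYR	CD1	C	CG
TYR	CD2	C	CG
TYR	CE1	C	CD1
TYR	CE2	C	CD2
TYR	CZ	C	CE1
TYR	OH	O	CZ
TYR	HH	H	OH
VAL	N	N	-
VAL	H	H	N
VAL	CA	C	N
VAL	C	C	CA
VAL	O	O	C
VAL	CB	C	CA
VAL	CG1	C	CB
VAL	CG2	C	CB
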