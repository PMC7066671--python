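# Residue/atom-name -> pharmacophore channel table for protein voxelization.
# Channels: hydrophobic, aromatic, hbond_acceptor, hbond_donor,
#           positive_ionizable, negative_ionizable, metallic, excluded_volume.
# The excluded_volume flag is added in code for every heavy atom; element-level
# rules in code add: C -> hydrophobic, metal elements -> metallic.
# Wildcard residue "*" matches any known residue (backbone atoms).
# residue	atom_name	channels
*	N	hbond_donor
*	O	hbond_acceptor
*	OXT	hbond_acceptor
PRO	N	-
ARG	NE	hbond_donor,positive_ionizable
ARG	NH1	hbond_donor,positive_ionizable
ARG	NH2	hbond_donor,positive_ionizable
ARG	CZ	positive_ionizable
LYS	NZ	hbond_donor,positive_ionizable
HIS	ND1	hbond_acceptor,hbond_donor,aromatic
HIS	NE2	hbond_acceptor,hbond_donor,aromatic
HIS	CG	aromatic
HIS	CD2	aromatic
HIS	CE1	aromatic
ASP	OD1	hbond_acceptor,negative_ionizable
ASP	OD2	hbond_acceptor,negative_ionizable
GLU	OE1	hbond_acceptor,negative_ionizable
GLU	OE2	hbond_acceptor,negative_ionizable
ASN	OD1	hbond_acceptor
ASN	ND2	hbond_donor
GLN	OE1	hbond_acceptor
GLN	NE2	hbond_donor
SER	OG	hbond_acceptor,hbond_donor
THR	OG1	hbond_acceptor,hbond_donor
TYR	OH	hbond_acceptor,hbond_donor
TYR	CG	aromatic
TYR	CD1	aromatic
TYR	CD2	aromatic
TYR	CE1	aromatic
TYR	CE2	aromatic
TYR	CZ	aromatic
PHE	CG	aromatic
PHE	CD1	aromatic
PHE	CD2	aromatic
PHE	CE1	aromatic
PHE	CE2	aromatic
PHE	CZ	aromatic
TRP	CG	aromatic
TRP	CD1	aromatic
TRP	CD2	aromatic
TRP	NE1	hbond_donor,aromatic
TRP	CE2	aromatic
TRP	CE3	aromatic
TRP	CZ2	aromatic
TRP	CZ3	aromatic
TRP	CH2	aromatic
CYS	SG	hbond_donor
MET	SD	hbond_acceptor
ALA	-	-
GLY	-	-
VAL	-	-
LEU	-	-
ILE	-	-
ZN	ZN	metallic
MG	MG	metallic
MN	MN	metallic
FE	FE	metallic
NA	NA	metallic
K	K	metallic
CA	CA	metallic
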