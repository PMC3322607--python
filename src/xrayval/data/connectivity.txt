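# Intra-residue covalent bonds for the standard amino acids and water.
# columns: RES A1 A2.  Backbone amide hydrogen is named H.
# The inter-residue peptide bond C(i)-N(i+1) is implied by the reader.
ALA N CA
ALA CA C
ALA C O
ALA CA CB
ALA N H
GLY N CA
GLY CA C
GLY C O
GLY N H
SER N CA
SER CA C
SER C O
SER CA CB
SER CB OG
SER N H
CYS N CA
CYS CA C
CYS C O
CYS CA CB
CYS CB SG
CYS N H
THR N CA
THR CA C
THR C O
THR CA CB
THR CB OG1
THR CB CG2
THR N H
VAL N CA
VAL CA C
VAL C O
VAL CA CB
VAL CB CG1
VAL CB CG2
VAL N H
LEU N CA
LEU CA C
LEU C O
LEU CA CB
LEU CB CG
LEU CG CD1
LEU CG CD2
LEU N H
ILE N CA
ILE CA C
ILE C O
ILE CA CB
ILE CB CG1
ILE CB CG2
ILE CG1 CD1
ILE N H
PRO N CA
PRO CA C
PRO C O
PRO CA CB
PRO CB CG
PRO CG CD
PRO CD N
MET N CA
MET CA C
MET C O
MET CA CB
MET CB CG
MET CG SD
MET SD CE
MET N H
PHE N CA
PHE CA C
PHE C O
PHE CA CB
PHE CB CG
PHE CG CD1
PHE CG CD2
PHE CD1 CE1
PHE CD2 CE2
PHE CE1 CZ
PHE CE2 CZ
PHE N H
TYR N CA
TYR CA C
TYR C O
TYR CA CB
TYR CB CG
TYR CG CD1
TYR CG CD2
TYR CD1 CE1
TYR CD2 CE2
TYR CE1 CZ
TYR CE2 CZ
TYR CZ OH
TYR N H
TRP N CA
TRP CA C
TRP C O
TRP CA CB
TRP CB CG
TRP CG CD1
TRP CG CD2
TRP CD1 NE1
TRP NE1 CE2
TRP CD2 CE2
TRP CD2 CE3
TRP CE2 CZ2
TRP CE3 CZ3
TRP CZ2 CH2
TRP CZ3 CH2
TRP N H
ASP N CA
ASP CA C
ASP C O
ASP CA CB
ASP CB CG
ASP CG OD1
ASP CG OD2
ASP N H
ASN N CA
ASN CA C
ASN C O
ASN CA CB
ASN CB CG
ASN CG OD1
ASN CG ND2
ASN N H
GLU N CA
GLU CA C
GLU C O
GLU CA CB
GLU CB CG
GLU CG CD
GLU CD OE1
GLU CD OE2
GLU N H
GLN N CA
GLN CA C
GLN C O
GLN CA CB
GLN CB CG
GLN CG CD
GLN CD OE1
GLN CD NE2
GLN N H
LYS N CA
LYS CA C
LYS C O
LYS CA CB
LYS CB CG
LYS CG CD
LYS CD CE
LYS CE NZ
LYS N H
ARG N CA
ARG CA C
ARG C O
ARG CA CB
ARG CB CG
ARG CG CD
ARG CD NE
ARG NE CZ
ARG CZ NH1
ARG CZ NH2
ARG N H
HIS N CA
HIS CA C
HIS C O
HIS CA CB
HIS CB CG
HIS CG ND1
HIS CG CD2
HIS ND1 CE1
HIS CD2 NE2
HIS CE1 NE2
HIS N H
HOH O H1
HOH O H2
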