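# Representative united-atom partial charges (elementary charges) for
# standard amino-acid heavy atoms, written for this package as a pluggable
# stand-in labeling scheme. Resname '*' matches any residue (backbone).
# Atoms not listed default to 0.0 (apolar carbons in a united-atom scheme).
resname,atomname,charge
*,N,-0.280
*,CA,0.000
*,C,0.380
*,O,-0.380
*,OXT,-0.635
ARG,CD,0.090
ARG,NE,-0.110
ARG,CZ,0.340
ARG,NH1,0.240
ARG,NH2,0.240
ASN,CG,0.380
ASN,OD1,-0.380
ASN,ND2,-0.280
ASP,CG,0.270
ASP,OD1,-0.635
ASP,OD2,-0.635
CYS,CB,0.150
CYS,SG,-0.064
GLN,CD,0.380
GLN,OE1,-0.380
GLN,NE2,-0.280
GLU,CD,0.270
GLU,OE1,-0.635
GLU,OE2,-0.635
HIS,CB,0.000
HIS,CG,0.000
HIS,ND1,-0.050
HIS,CD2,0.000
HIS,CE1,0.100
HIS,NE2,-0.050
LYS,CE,0.127
LYS,NZ,0.129
MET,CG,0.060
MET,SD,-0.120
MET,CE,0.060
SER,CB,0.150
SER,OG,-0.548
THR,CB,0.150
THR,OG1,-0.548
TRP,CD1,0.060
TRP,NE1,-0.120
TRP,CE2,0.060
TYR,CZ,0.150
TYR,OH,-0.548
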