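# Side-chain chi definitions and rotamer chi-angle modes (degrees).
# chidef  RES chiN A1 A2 A3 A4    -- four atoms defining the torsion
# rotamer RES NAME chi1 [chi2 ...]
# Modes are coarse penultimate-style canonical values; residues without
# chi atoms (GLY, ALA) are absent and are reported as not-evaluated.
chidef SER chi1 N CA CB OG
chidef CYS chi1 N CA CB SG
chidef THR chi1 N CA CB OG1
chidef VAL chi1 N CA CB CG1
chidef ILE chi1 N CA CB CG1
chidef ILE chi2 CA CB CG1 CD1
chidef LEU chi1 N CA CB CG
chidef LEU chi2 CA CB CG CD1
chidef ASP chi1 N CA CB CG
chidef ASP chi2 CA CB CG OD1
chidef ASN chi1 N CA CB CG
chidef ASN chi2 CA CB CG OD1
chidef HIS chi1 N CA CB CG
chidef HIS chi2 CA CB CG ND1
chidef PHE chi1 N CA CB CG
chidef PHE chi2 CA CB CG CD1
chidef TYR chi1 N CA CB CG
chidef TYR chi2 CA CB CG CD1
chidef TRP chi1 N CA CB CG
chidef TRP chi2 CA CB CG CD1
chidef MET chi1 N CA CB CG
chidef MET chi2 CA CB CG SD
chidef MET chi3 CB CG SD CE
chidef GLU chi1 N CA CB CG
chidef GLU chi2 CA CB CG CD
chidef GLU chi3 CB CG CD OE1
chidef GLN chi1 N CA CB CG
chidef GLN chi2 CA CB CG CD
chidef GLN chi3 CB CG CD OE1
chidef LYS chi1 N CA CB CG
chidef LYS chi2 CA CB CG CD
chidef LYS chi3 CB CG CD CE
chidef LYS chi4 CG CD CE NZ
chidef ARG chi1 N CA CB CG
chidef ARG chi2 CA CB CG CD
chidef ARG chi3 CB CG CD NE
chidef ARG chi4 CG CD NE CZ
chidef PRO chi1 N CA CB CG
chidef PRO chi2 CA CB CG CD
rotamer SER p 60
rotamer SER t 180
rotamer SER m -60
rotamer CYS p 60
rotamer CYS t 180
rotamer CYS m -60
rotamer THR p 60
rotamer THR t 180
rotamer THR m -60
rotamer VAL p 60
rotamer VAL t 180
rotamer VAL m -60
rotamer ILE pt 60 170
rotamer ILE mt -60 170
rotamer ILE mm -60 -60
rotamer ILE tt 180 170
rotamer LEU mt -65 175
rotamer LEU tp 180 65
rotamer LEU tt 180 180
rotamer ASP m-20 -70 -20
rotamer ASP t0 180 0
rotamer ASP p-10 60 -10
rotamer ASN m-40 -65 -40
rotamer ASN t0 180 0
rotamer ASN p-10 60 -10
rotamer HIS m-70 -65 -70
rotamer HIS t60 180 60
rotamer HIS p80 60 80
rotamer PHE m-85 -65 -85
rotamer PHE t80 180 80
rotamer PHE p90 60 90
rotamer TYR m-85 -65 -85
rotamer TYR t80 180 80
rotamer TYR p90 60 90
rotamer TRP m-90 -65 -90
rotamer TRP t-105 180 -105
rotamer TRP p90 60 90
rotamer MET mmm -65 -65 -70
rotamer MET mtp -65 180 75
rotamer MET ttt 180 180 180
rotamer GLU mt-10 -65 180 -10
rotamer GLU tt0 180 180 0
rotamer GLU pt-20 60 180 -20
rotamer GLN mt-30 -65 180 -30
rotamer GLN tt0 180 180 0
rotamer GLN pt20 60 180 20
rotamer LYS mttt -65 180 180 180
rotamer LYS tttt 180 180 180 180
rotamer LYS ptpt 60 180 60 180
rotamer ARG mtt180 -65 180 180 180
rotamer ARG ttt180 180 180 180 180
rotamer ARG ptt180 60 180 180 180
rotamer PRO endo -25 40
rotamer PRO exo 25 -35
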