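# Covalent-geometry restraint dictionary (Engh & Huber style).
# bond  RES A1 A2      mean_A   sd_A
# angle RES A1 A2 A3   mean_deg sd_deg
# Residue name PEPTIDE keys the inter-residue link: atoms of the
# preceding residue are suffixed '-', of the following '+'.
bond  ALA N CA   1.458 0.019
bond  ALA CA C   1.525 0.021
bond  ALA C O    1.231 0.020
bond  ALA CA CB  1.530 0.020
angle ALA N CA C    111.2 2.8
angle ALA N CA CB   110.4 1.8
angle ALA CB CA C   110.5 1.8
bond  ARG N CA   1.458 0.019
bond  ARG CA C   1.525 0.021
bond  ARG C O    1.231 0.020
bond  ARG CA CB  1.530 0.020
angle ARG N CA C    111.2 2.8
angle ARG N CA CB   110.4 1.8
angle ARG CB CA C   110.5 1.8
bond  ASN N CA   1.458 0.019
bond  ASN CA C   1.525 0.021
bond  ASN C O    1.231 0.020
bond  ASN CA CB  1.530 0.020
angle ASN N CA C    111.2 2.8
angle ASN N CA CB   110.4 1.8
angle ASN CB CA C   110.5 1.8
bond  ASP N CA   1.458 0.019
bond  ASP CA C   1.525 0.021
bond  ASP C O    1.231 0.020
bond  ASP CA CB  1.530 0.020
angle ASP N CA C    111.2 2.8
angle ASP N CA CB   110.4 1.8
angle ASP CB CA C   110.5 1.8
bond  CYS N CA   1.458 0.019
bond  CYS CA C   1.525 0.021
bond  CYS C O    1.231 0.020
bond  CYS CA CB  1.530 0.020
angle CYS N CA C    111.2 2.8
angle CYS N CA CB   110.4 1.8
angle CYS CB CA C   110.5 1.8
bond  GLN N CA   1.458 0.019
bond  GLN CA C   1.525 0.021
bond  GLN C O    1.231 0.020
bond  GLN CA CB  1.530 0.020
angle GLN N CA C    111.2 2.8
angle GLN N CA CB   110.4 1.8
angle GLN CB CA C   110.5 1.8
bond  GLU N CA   1.458 0.019
bond  GLU CA C   1.525 0.021
bond  GLU C O    1.231 0.020
bond  GLU CA CB  1.530 0.020
angle GLU N CA C    111.2 2.8
angle GLU N CA CB   110.4 1.8
angle GLU CB CA C   110.5 1.8
bond  GLY N CA   1.458 0.019
bond  GLY CA C   1.525 0.021
bond  GLY C O    1.231 0.020
angle GLY N CA C    111.2 2.8
bond  HIS N CA   1.458 0.019
bond  HIS CA C   1.525 0.021
bond  HIS C O    1.231 0.020
bond  HIS CA CB  1.530 0.020
angle HIS N CA C    111.2 2.8
angle HIS N CA CB   110.4 1.8
angle HIS CB CA C   110.5 1.8
bond  ILE N CA   1.458 0.019
bond  ILE CA C   1.525 0.021
bond  ILE C O    1.231 0.020
bond  ILE CA CB  1.530 0.020
angle ILE N CA C    111.2 2.8
angle ILE N CA CB   110.4 1.8
angle ILE CB CA C   110.5 1.8
bond  LEU N CA   1.458 0.019
bond  LEU CA C   1.525 0.021
bond  LEU C O    1.231 0.020
bond  LEU CA CB  1.530 0.020
angle LEU N CA C    111.2 2.8
angle LEU N CA CB   110.4 1.8
angle LEU CB CA C   110.5 1.8
bond  LYS N CA   1.458 0.019
bond  LYS CA C   1.525 0.021
bond  LYS C O    1.231 0.020
bond  LYS CA CB  1.530 0.020
angle LYS N CA C    111.2 2.8
angle LYS N CA CB   110.4 1.8
angle LYS CB CA C   110.5 1.8
bond  MET N CA   1.458 0.019
bond  MET CA C   1.525 0.021
bond  MET C O    1.231 0.020
bond  MET CA CB  1.530 0.020
angle MET N CA C    111.2 2.8
angle MET N CA CB   110.4 1.8
angle MET CB CA C   110.5 1.8
bond  PHE N CA   1.458 0.019
bond  PHE CA C   1.525 0.021
bond  PHE C O    1.231 0.020
bond  PHE CA CB  1.530 0.020
angle PHE N CA C    111.2 2.8
angle PHE N CA CB   110.4 1.8
angle PHE CB CA C   110.5 1.8
bond  PRO N CA   1.466 0.015
bond  PRO CA C   1.525 0.021
bond  PRO C O    1.231 0.020
bond  PRO CA CB  1.530 0.020
angle PRO N CA C    111.2 2.8
angle PRO N CA CB   110.4 1.8
angle PRO CB CA C   110.5 1.8
bond  SER N CA   1.458 0.019
bond  SER CA C   1.525 0.021
bond  SER C O    1.231 0.020
bond  SER CA CB  1.530 0.020
angle SER N CA C    111.2 2.8
angle SER N CA CB   110.4 1.8
angle SER CB CA C   110.5 1.8
bond  THR N CA   1.458 0.019
bond  THR CA C   1.525 0.021
bond  THR C O    1.231 0.020
bond  THR CA CB  1.530 0.020
angle THR N CA C    111.2 2.8
angle THR N CA CB   110.4 1.8
angle THR CB CA C   110.5 1.8
bond  TRP N CA   1.458 0.019
bond  TRP CA C   1.525 0.021
bond  TRP C O    1.231 0.020
bond  TRP CA CB  1.530 0.020
angle TRP N CA C    111.2 2.8
angle TRP N CA CB   110.4 1.8
angle TRP CB CA C   110.5 1.8
bond  TYR N CA   1.458 0.019
bond  TYR CA C   1.525 0.021
bond  TYR C O    1.231 0.020
bond  TYR CA CB  1.530 0.020
angle TYR N CA C    111.2 2.8
angle TYR N CA CB   110.4 1.8
angle TYR CB CA C   110.5 1.8
bond  VAL N CA   1.458 0.019
bond  VAL CA C   1.525 0.021
bond  VAL C O    1.231 0.020
bond  VAL CA CB  1.530 0.020
angle VAL N CA C    111.2 2.8
angle VAL N CA CB   110.4 1.8
angle VAL CB CA C   110.5 1.8
bond  PEPTIDE C- N+        1.329 0.014
angle PEPTIDE CA- C- N+    116.2 2.0
angle PEPTIDE O- C- N+     123.0 1.6
angle PEPTIDE CA- C- O-    120.8 1.7
angle PEPTIDE C- N+ CA+    121.7 1.8
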