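# Ramachandran region grid, 10-degree bins over (-180,180]^2.
# One line per (category, phi bin): category phi_low then 36 labels,
# one char per psi bin from psi=-180 upward: F favored, A allowed, O outlier.
# Cell label = membership of the cell centre in the analytic region set.
general -180 AOOOOOOOOOOOOOOOOOOOOOOOOOAAAAAAAAAA
general -170 AOOOOOOOOOOOOOOOOOOOOOOOOOAAAAFFFAAA
general -160 AAOOOOOOOOOOOOOOOOOOOOOOOAAAFFFFFFFA
general -150 AAOOOOOOOOOOOOOOOOOOOOOOOAAAFFFFFFFA
general -140 AAAOOOOOOOOOOOOOOOOOOOOOAAAFFFFFFFFF
general -130 AAAOOOOOOOOOOOOOOOOOOOOOAAAFFFFFFFFF
general -120 AAAOOOOOOOOOOOOOOOOOOOOOAAAFFFFFFFFF
general -110 AAAOOOOOOOAAAAAAAOOOOOOOAAAFFFFFFFFF
general -100 AAAOOOOOOAAAAAAAAAOOOOOOAAAFFFFFFFFF
general -90 AAOOOOOOOAAFFFFFAAAOOOOOOAAAFFFFFFFA
general -80 AAOOOOOOAAFFFFFFFAAOOOOOOAAAFFFFFFFA
general -70 AOOOOOOOAAFFFFFFFAAOOOOOOOAAAAFFFAAA
general -60 AOOOOOOOAAFFFFFFFAAOOOOOOOAAAAAAAAAA
general -50 OOOOOOOOAAAFFFFFFAAOOOOOOOOAAAAAAAAA
general -40 OOOOOOOOOAAAFFFAAAOOOOOOOOOOOAAAAAOO
general -30 OOOOOOOOOOAAAAAAAOOOOOOOOOOOOOOOOOOO
general -20 OOOOOOOOOOOOAAAAOOOOOOOOOOOOOOOOOOOO
general -10 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 0 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 10 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 20 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 30 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 40 OOOOOOOOOOOOOOOOOOOOOAAOOOOOOOOOOOOO
general 50 OOOOOOOOOOOOOOOOOOOOOAAOOOOOOOOOOOOO
general 60 OOOOOOOOOOOOOOOOOOOOOAAOOOOOOOOOOOOO
general 70 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 80 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 90 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 100 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 110 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 120 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 130 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 140 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 150 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
general 160 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOAAAAAOO
general 170 OOOOOOOOOOOOOOOOOOOOOOOOOOOAAAAAAAAA
GLY -180 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOAAAAAA
GLY -170 AAOOOOOOOOOOOOOOOOOOOOOOOOOOAAAAAAAA
GLY -160 AAOOOOOOOOOOOOOOOOOOOOOOOOOOAAAAAAAA
GLY -150 AAAOOOOOOOOOOOOOOOOOOOOOOOOAAAAAAAAA
GLY -140 AAAAOOOOOOOOOOOOOOOOOOOOOOAAAAFFFFFF
GLY -130 AAAAOOOOOOOOOOOOOOOOOOOOOOAAAAFFFFFF
GLY -120 FAAAOOOOOOAAAAAAAOOOOOOOOOAAAFFFFFFF
GLY -110 FAAAAOOOOAAAAAAAAAAOOOOOOAAAAFFFFFFF
GLY -100 FAAAAOOOAAAAFFFAAAAOOOOOOAAAAFFFFFFF
GLY -90 FAAAAOOAAAAFFFFFFAAAOOOOOAAAAFFFFFFF
GLY -80 FAAAAOOAAAFFFFFFFAAAOOOOOAAAAFFFFFFF
GLY -70 FAAAOOOAAAFFFFFFFFAAOOOOOOAAAFFFFFFF
GLY -60 AAAAOOOAAAFFFFFFFFAAOOOOOOAAAAFFFFFF
GLY -50 AAAAOOOAAAFFFFFFFAAAOOOOOOAAAAFFFFFF
GLY -40 AAAOOOOOAAAFFFFFAAAAOOOOOOOAAAAAAAAA
GLY -30 AAOOOOOOAAAAAAAAAAAOOOOOOOOOAAAAAAAA
GLY -20 AAOOOOOOOOAAAAAAAAOOOOOOOOOOAAAAAAAA
GLY -10 OOOOOOOOOOOOAAAOOOOOOOOOOOOOOOAAAAAA
GLY 0 AAAAAAOOOOOOOOOOOOOOOAAAOOOOOOOOOOOO
GLY 10 AAAAAAAAOOOOOOOOOOAAAAAAAAOOOOOOOOAA
GLY 20 AAAAAAAAOOOOOOOOOAAAAAAAAAAAOOOOOOAA
GLY 30 AAAAAAAAAOOOOOOOAAAAFFFFFAAAOOOOOAAA
GLY 40 FFFFFFAAAAOOOOOOAAAFFFFFFFAAAOOOAAAA
GLY 50 FFFFFFAAAAOOOOOOAAFFFFFFFFAAAOOOAAAA
GLY 60 FFFFFFFAAAOOOOOOAAFFFFFFFFAAAOOOAAAF
GLY 70 FFFFFFFAAAAOOOOOAAAFFFFFFFAAAOOAAAAF
GLY 80 FFFFFFFAAAAOOOOOAAAFFFFFFAAAAOOAAAAF
GLY 90 FFFFFFFAAAAOOOOOOAAAAFFFAAAAOOOAAAAF
GLY 100 FFFFFFFAAAAOOOOOOAAAAAAAAAAOOOOAAAAF
GLY 110 FFFFFFFAAAOOOOOOOOOAAAAAAAOOOOOOAAAF
GLY 120 FFFFFFAAAAOOOOOOOOOOOOOOOOOOOOOOAAAA
GLY 130 FFFFFFAAAAOOOOOOOOOOOOOOOOOOOOOOAAAA
GLY 140 AAAAAAAAAOOOOOOOOOOOOOOOOOOOOOOOOAAA
GLY 150 AAAAAAAAOOOOOOOOOOOOOOOOOOOOOOOOOOAA
GLY 160 AAAAAAAAOOOOOOOOOOOOOOOOOOOOOOOOOOAA
GLY 170 AAAAAAOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO -180 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO -170 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO -160 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO -150 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO -140 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO -130 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO -120 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO -110 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO -100 OOOOOOOOOOOOAAAAAOOOOOOOOOOOOAAAAAAA
PRO -90 AAOOOOOOOOOAAAFAAAOOOOOOOOOAAAAFFFAA
PRO -80 AAOOOOOOOOAAFFFFFAAOOOOOOOOAAFFFFFFF
PRO -70 AAAOOOOOOOAAFFFFFAAOOOOOOOAAAFFFFFFF
PRO -60 AAAOOOOOOOAAFFFFFAAOOOOOOOAAAFFFFFFF
PRO -50 AAOOOOOOOOAAFFFFFAAOOOOOOOOAAFFFFFFF
PRO -40 AOOOOOOOOOOAAAAAAAOOOOOOOOOOAAAAAAAA
PRO -30 OOOOOOOOOOOOAAAAAOOOOOOOOOOOOOAAAAAO
PRO -20 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO -10 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 0 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 10 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 20 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 30 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 40 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 50 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 60 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 70 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 80 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 90 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 100 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 110 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 120 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 130 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 140 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 150 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 160 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
PRO 170 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO -180 AOOOOOOOOOOOOOOOOOOOOOOOOAAAAAAAAAAA
prePRO -170 AAOOOOOOOOOOOOOOOOOOOOOOAAAAFFFFFFAA
prePRO -160 AAOOOOOOOOOOOOOOOOOOOOOOAAAFFFFFFFFA
prePRO -150 AAAOOOOOOOOOOOOOOOOOOOOAAAAFFFFFFFFA
prePRO -140 AAAOOOOOOOOOOOOOOOOOOOOAAAFFFFFFFFFF
prePRO -130 AAAOOOOOOOOOOOOOOOOOOOOAAAFFFFFFFFFF
prePRO -120 AAAOOOOOOOOOOOOOOOOOOOOAAAFFFFFFFFFF
prePRO -110 AAAOOOOOOOOAAAAAOOOOOOOAAAFFFFFFFFFF
prePRO -100 AAAOOOOOOOAAAAAAAAOOOOOAAAAFFFFFFFFA
prePRO -90 AAOOOOOOOAAFFFFFAAOOOOOOAAAFFFFFFFFA
prePRO -80 AAOOOOOOOAAFFFFFFAAOOOOOAAAAFFFFFFAA
prePRO -70 AOOOOOOOAAFFFFFFFAAOOOOOOAAAAAAAAAAA
prePRO -60 OOOOOOOOAAAFFFFFFAAOOOOOOOAAAAAAAAAA
prePRO -50 OOOOOOOOOAAFFFFFAAAOOOOOOOOAAAAAAAAO
prePRO -40 OOOOOOOOOAAAAFFAAAOOOOOOOOOOOAAAAOOO
prePRO -30 OOOOOOOOOOAAAAAAAOOOOOOOOOOOOOOOOOOO
prePRO -20 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO -10 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO 0 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO 10 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO 20 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO 30 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO 40 OOOOOOOOOOOOOOOOOOOOOAAOOOOOOOOOOOOO
prePRO 50 OOOOOOOOOOOOOOOOOOOOOAAOOOOOOOOOOOOO
prePRO 60 OOOOOOOOOOOOOOOOOOOOOAAOOOOOOOOOOOOO
prePRO 70 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO 80 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO 90 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO 100 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO 110 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO 120 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO 130 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO 140 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
prePRO 150 OOOOOOOOOOOOOOOOOOOOOOOOOOOOOAAAAOOO
prePRO 160 OOOOOOOOOOOOOOOOOOOOOOOOOOOAAAAAAAAO
prePRO 170 OOOOOOOOOOOOOOOOOOOOOOOOOOAAAAAAAAAA
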