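# Bundled European-origin-style KIR gene-content haplotype library (synthetic).
# Signatures are per-locus copy counts in the marker order below; 2DS4 is
# split into its full-length (FL) and 22-bp-deletion (del) variants.
# The ped1416_* entries emulate the eight haplotypes (a-d, w-z) deduced by
# segregation analysis in a reference pedigree; ped1416_c carries the
# duplication of 3DP1, 2DL4 and the 3DL1/S1 locus.  del_3DL1_3DL2 emulates a
# contracted haplotype with a deletion from 3DL1 through to 3DL2.
# Counts and frequencies are documented placeholders, not published values.
# marker_order: 3DL3,2DS2,2DL2,2DL3,2DP1,2DL1,3DP1,2DL4,3DL1,3DS1,2DL5,2DS3,2DS5,2DS4FL,2DS4del,2DS1,3DL2
haplotype_id,signature,count,frequency,cen_motif,tel_motif
cA01,1-0-0-1-1-1-1-1-1-0-0-0-0-0-1-0-1,545,0.545,cA01,tA01
cA02,1-0-0-1-1-1-1-1-1-0-0-0-0-1-0-0-1,60,0.06,cA01,tA02
cB01,1-1-1-0-1-1-1-1-0-1-1-1-0-0-0-1-1,170,0.17,cB01,tB01
cB02,1-1-1-0-1-1-1-1-1-0-1-0-1-1-0-1-1,100,0.10,cB01,tA01
ped1416_a,1-0-0-1-1-1-1-1-1-0-0-0-0-0-1-0-1,20,0.020,cA01,tA01
ped1416_b,1-1-1-0-1-1-1-1-0-1-1-0-1-0-0-1-1,20,0.020,cB01,tB01
ped1416_c,1-1-1-0-1-1-2-2-1-1-1-1-0-0-0-0-1,5,0.005,cB02,tB03
ped1416_d,1-0-0-1-1-1-1-1-1-0-0-0-0-1-0-0-1,20,0.020,cA01,tA02
ped1416_w,1-1-0-1-1-1-1-1-1-0-1-0-1-1-0-1-1,10,0.010,cA01,tB01
ped1416_x,1-0-0-1-1-1-1-1-1-0-0-0-0-0-1-0-1,10,0.010,cA01,tA01
ped1416_y,1-1-1-0-1-1-1-1-0-1-1-1-0-0-0-1-1,10,0.010,cB01,tB01
ped1416_z,1-0-0-1-1-1-1-1-1-0-0-0-0-0-1-0-1,10,0.010,cA01,tA01
del_3DL1_3DL2,1-1-1-0-1-1-1-1-0-0-0-0-0-0-0-0-1,20,0.020,cB01,tDel
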