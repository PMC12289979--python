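game,matrix_id,T,R,P,S,category,stake_level,shift
PD,PD_s0_m00,7.0,5.0,3.0,2.0,C1,0,0.0
PD,PD_s0_m01,4.0,2.0,0.0,-1.0,C2,0,3.0
PD,PD_s0_m02,3.0,1.0,-1.0,-2.0,C3,0,4.0
PD,PD_s0_m03,1.0,-1.0,-3.0,-4.0,C4,0,6.0
PD,PD_s0_m04,-3.0,-5.0,-7.0,-8.0,C5,0,10.0
SH,SH_s0_m00,5.0,7.0,3.0,2.0,C1,0,0.0
SH,SH_s0_m01,2.0,4.0,0.0,-1.0,C2,0,3.0
SH,SH_s0_m02,1.0,3.0,-1.0,-2.0,C3,0,4.0
SH,SH_s0_m03,-1.0,1.0,-3.0,-4.0,C4,0,6.0
SH,SH_s0_m04,-5.0,-3.0,-7.0,-8.0,C5,0,10.0
CH,CH_s0_m00,7.0,5.0,2.0,3.0,C1,0,0.0
CH,CH_s0_m01,4.0,2.0,-1.0,0.0,C2,0,3.0
CH,CH_s0_m02,3.0,1.0,-2.0,-1.0,C3,0,4.0
CH,CH_s0_m03,1.0,-1.0,-4.0,-3.0,C4,0,6.0
CH,CH_s0_m04,-3.0,-5.0,-8.0,-7.0,C5,0,10.0
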