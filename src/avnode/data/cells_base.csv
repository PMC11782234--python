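id,segment,a1,a2,k,c,eps0,mu1,mu2,is_pacemaker,gamma_controlled
SN1,SN,-0.08965673828125,0.2,8.0,1.0,0.0075,0.01,0.2,1,1
SN2,SN,-0.08965673828125,0.2,8.0,1.0,0.0075,0.01,0.2,1,1
PS1,PS,0.06,0.1,8.0,0.5,0.007,0.3,0.3,0,1
PS2,PS,0.06,0.1,8.0,0.5,0.007,0.3,0.3,0,1
AM1,AM,0.08,0.1,8.0,0.55,0.007,0.3,0.3,0,1
AM2,AM,0.08,0.1,8.0,0.55,0.007,0.3,0.3,0,1
AM3,AM,0.08,0.1,8.0,0.55,0.007,0.3,0.3,0,1
FP1,FP,0.1,0.1,8.0,0.5,0.006,0.075,0.3,0,1
FP2,FP,0.1,0.1,8.0,0.5,0.006,0.075,0.3,0,1
FP3,FP,0.1,0.1,8.0,0.5,0.006,0.075,0.3,0,1
FP4,FP,0.1,0.1,8.0,0.5,0.006,0.075,0.3,0,1
FP5,FP,0.1,0.1,8.0,0.5,0.006,0.075,0.3,0,1
FP6,FP,0.1,0.1,8.0,0.5,0.006,0.075,0.3,0,1
FP7,FP,0.1,0.1,8.0,0.5,0.006,0.075,0.3,0,1
FP8,FP,0.1,0.1,8.0,0.5,0.006,0.075,0.3,0,1
SP1,SP,0.07,0.1,8.0,0.6,0.008,0.15,0.3,0,1
SP2,SP,0.07,0.1,8.0,0.6,0.008,0.15,0.3,0,1
SP3,SP,0.07,0.1,8.0,0.6,0.008,0.15,0.3,0,1
SP4,SP,0.07,0.1,8.0,0.6,0.008,0.15,0.3,0,1
SP5,SP,0.07,0.1,8.0,0.6,0.008,0.15,0.3,0,1
SP6,SP,0.07,0.1,8.0,0.6,0.008,0.15,0.3,0,1
SP7,SP,0.07,0.1,8.0,0.6,0.008,0.15,0.3,0,1
SP8,SP,0.07,0.1,8.0,0.6,0.008,0.15,0.3,0,1
SP9,SP,-0.004,0.1,8.0,0.6,0.008,0.15,0.3,1,1
SP10,SP,0.07,0.1,8.0,0.6,0.008,0.15,0.3,0,1
PB1,PB,0.13,0.1,8.0,0.5,0.006,0.2,0.3,0,1
HB1,HB,0.13,0.1,8.0,0.55,0.006,0.35,0.3,0,0
HB2,HB,0.13,0.1,8.0,0.55,0.006,0.35,0.3,0,0
HB3,HB,0.13,0.1,8.0,0.55,0.006,0.35,0.3,0,0
HB4,HB,0.13,0.1,8.0,0.55,0.006,0.35,0.3,0,0
HB5,HB,0.13,0.1,8.0,0.55,0.006,0.35,0.3,0,0
HB6,HB,0.13,0.1,8.0,0.55,0.006,0.35,0.3,0,0
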