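from_cell,to_cell,d,beta
SN1,SN2,0.4,1.0
SN2,PS1,0.25,1.0
PS1,PS2,0.5,1.0
PS2,AM1,0.5,1.0
AM1,AM2,0.5,1.0
AM2,AM3,0.5,1.0
AM3,FP1,0.25,0.75
FP1,FP2,0.25,0.75
FP2,FP3,0.25,0.75
FP3,FP4,0.25,0.75
FP4,FP5,0.25,0.75
FP5,FP6,0.25,0.75
FP6,FP7,0.25,0.75
FP7,FP8,0.25,0.75
FP8,PB1,0.25,0.75
AM3,SP1,0.08,0.9
SP1,SP2,0.1,0.9
SP2,SP3,0.1,0.9
SP3,SP4,0.1,0.9
SP4,SP5,0.1,0.9
SP5,SP6,0.1,0.9
SP6,SP7,0.1,0.9
SP7,SP8,0.1,0.9
SP8,SP9,0.1,0.9
SP9,SP10,0.1,0.9
SP10,PB1,0.25,0.9
PB1,HB1,0.5,1.0
HB1,HB2,0.5,1.0
HB2,HB3,0.5,1.0
HB3,HB4,0.5,1.0
HB4,HB5,0.5,1.0
HB5,HB6,0.5,1.0
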