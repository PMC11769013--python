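# Published displayed box limits (2-decimal inclusive bounds) of the 9-box grid,
# as derived from the reference percentiles of 802 healthy / 2967 total dogs.
parameter,box1_lower,box1_upper,box2_lower,box2_upper,box3_lower,box3_upper,box4_lower,box4_upper,box5_lower,box5_upper,box6_lower,box6_upper,box7_lower,box7_upper,box8_lower,box8_upper,box9_lower,box9_upper
AIDn,0.35,0.41,0.42,0.48,0.49,0.55,0.56,0.70,0.71,0.85,0.86,1.00,1.01,1.26,1.27,1.52,1.53,2.22
IVSSDn,0.22,0.24,0.25,0.26,0.27,0.28,0.29,0.39,0.40,0.48,0.49,0.58,0.59,0.61,0.62,0.65,0.66,0.84
LVIDDn,0.68,0.82,0.83,0.96,0.97,1.11,1.12,1.31,1.32,1.50,1.51,1.69,1.70,2.07,2.08,2.46,2.47,3.04
PLVWDn,0.19,0.21,0.22,0.23,0.24,0.25,0.26,0.38,0.39,0.50,0.51,0.62,0.63,0.63,0.64,0.65,0.66,0.86
IVSSn,0.11,0.21,0.22,0.32,0.33,0.42,0.43,0.56,0.57,0.69,0.70,0.82,0.83,0.85,0.86,0.90,0.91,1.22
LVIDSn,0.24,0.31,0.32,0.39,0.40,0.46,0.47,0.67,0.68,0.86,0.87,1.06,1.07,1.32,1.33,1.58,1.59,2.55
PLVWSn,0.32,0.35,0.36,0.38,0.39,0.40,0.41,0.55,0.56,0.69,0.70,0.83,0.84,0.86,0.87,0.89,0.90,1.12
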