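# Anchor percentiles of weight-normalised canine echocardiographic dimensions.
# Populations: HEALTHY n=802, TOTAL (healthy + cardiac pooled) n=2967; dogs under 20 kg.
parameter,population,n,min,p1,p2.5,p5,p25,p50,p75,p95,p97.5,p99,max
AIDn,HEALTHY,802,0.49,0.56,0.59,0.62,0.70,0.75,0.82,0.92,0.96,1.00,1.23
IVSSDn,HEALTHY,802,0.25,0.29,0.31,0.32,0.38,0.42,0.46,0.54,0.56,0.58,0.69
LVIDDn,HEALTHY,802,0.84,1.12,1.19,1.22,1.38,1.47,1.55,1.66,1.68,1.69,1.74
PLVWDn,HEALTHY,802,0.23,0.26,0.29,0.30,0.37,0.42,0.47,0.56,0.58,0.62,0.69
IVSSn,HEALTHY,802,0.33,0.43,0.43,0.46,0.54,0.59,0.64,0.74,0.77,0.82,0.92
LVIDSn,HEALTHY,802,0.28,0.47,0.54,0.58,0.73,0.82,0.90,1.01,1.04,1.06,1.09
PLVWSn,HEALTHY,802,0.37,0.41,0.44,0.47,0.54,0.61,0.68,0.77,0.80,0.83,0.95
AIDn,TOTAL,2967,0.35,0.58,0.61,0.64,0.73,0.80,0.91,1.20,1.37,1.52,2.22
IVSSDn,TOTAL,2967,0.22,0.28,0.30,0.32,0.38,0.43,0.48,0.56,0.60,0.65,0.84
LVIDDn,TOTAL,2967,0.68,1.07,1.16,1.22,1.41,1.54,1.69,2.12,2.29,2.46,3.04
PLVWDn,TOTAL,2967,0.19,0.27,0.29,0.31,0.38,0.43,0.49,0.57,0.61,0.65,0.86
IVSSn,TOTAL,2967,0.11,0.40,0.44,0.47,0.55,0.62,0.68,0.81,0.85,0.90,1.22
LVIDSn,TOTAL,2967,0.24,0.45,0.52,0.59,0.75,0.86,0.97,1.18,1.34,1.58,2.55
PLVWSn,TOTAL,2967,0.32,0.41,0.44,0.47,0.56,0.63,0.70,0.81,0.85,0.89,1.12
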