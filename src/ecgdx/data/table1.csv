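name,x1,x2,x3,x4,x5,x6,x7,x8,x9,x10,t1,t2,t3,t4,t5,t6,t7,t8
H1,1.000,0.672,0.155,0.000,0.045,0.057,0.049,0.049,0.053,0.055,1,0,0,0,0,0,0,0
H2,0.000,0.273,0.600,0.782,1.000,0.945,0.945,0.799,0.618,0.418,0,1,0,0,0,0,0,0
H3,0.485,0.449,0.147,0.007,0.007,0.000,0.169,0.632,1.000,0.757,0,0,1,0,0,0,0,0
H4,0.035,0.000,0.170,0.338,0.356,0.309,0.430,0.719,1.000,0.946,0,0,0,1,0,0,0,0
S1,1.000,0.740,0.228,0.000,0.045,0.091,0.098,0.101,0.104,0.107,0,0,0,0,1,0,0,0
S2,0.000,0.123,0.304,0.495,0.536,0.883,0.851,1.000,0.796,0.761,0,0,0,0,0,1,0,0
S3,0.044,0.000,0.045,0.319,0.748,1.000,0.868,0.440,0.154,0.050,0,0,0,0,0,0,1,0
S4,0.033,0.000,0.000,0.085,0.360,0.779,1.000,0.820,0.399,0.079,0,0,0,0,0,0,0,1
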