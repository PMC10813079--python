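velocity_m_s,0.50,0.75,1.00,1.25
0.053,1.68,1.24,1.00,0.85
0.106,1.61,1.21,1.00,0.86
0.159,1.58,1.20,1.00,0.87
0.212,1.54,1.19,1.00,0.88
0.265,1.52,1.19,1.00,0.88
0.318,1.51,1.18,1.00,0.88
0.371,1.50,1.18,1.00,0.88
0.424,1.49,1.18,1.00,0.89
0.476,1.48,1.17,1.00,0.89
0.529,1.47,1.17,1.00,0.89
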