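velocity_m_s,1.04,1.57,2.09,2.61,3.13,4.17
0.053,1.65,1.34,1.21,1.13,1.08,1.00
0.106,1.81,1.43,1.26,1.16,1.10,1.00
0.159,1.90,1.48,1.29,1.21,1.11,1.00
0.212,1.94,1.51,1.31,1.22,1.10,1.00
0.265,1.98,1.53,1.32,1.23,1.10,1.00
0.318,2.00,1.54,1.32,1.24,1.10,1.00
0.371,2.02,1.55,1.33,1.25,1.11,1.00
0.424,2.03,1.56,1.33,1.25,1.11,1.00
0.476,2.04,1.56,1.34,1.25,1.11,1.00
0.529,2.04,1.56,1.34,1.25,1.11,1.00
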