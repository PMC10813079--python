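velocity_m_s,0.70,0.86,0.96,1.00
0.053,1.36,1.13,1.05,1.00
0.106,1.25,1.09,1.03,1.00
0.159,1.20,1.07,1.03,1.00
0.212,1.17,1.05,1.02,1.00
0.265,1.15,1.05,1.01,1.00
0.318,1.13,1.04,1.00,1.00
0.371,1.11,1.04,1.00,1.00
0.424,1.10,1.03,0.99,1.00
0.476,1.10,1.03,0.99,1.00
0.529,1.09,1.03,0.99,1.00
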