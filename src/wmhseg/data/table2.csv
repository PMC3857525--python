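subject,rater1_vs_rater2,rater1_vs_semi_automated,rater2_vs_semi_automated
S1,0.83,0.81,0.96
S2,0.79,0.70,0.70
S3,0.84,0.88,0.76
S4,0.74,0.66,0.64
S5,0.75,0.71,0.93
S6,0.72,0.70,0.85
S7,0.74,0.73,0.67
S8,0.75,0.74,0.97
S9,0.97,0.93,0.96
S10,0.80,0.67,0.59
S11,0.83,0.74,0.66
S12,0.73,0.68,0.87
S13,0.71,0.67,0.85
S14,0.72,0.70,0.68
S15,0.79,0.79,0.93
S16,0.91,0.94,0.93
S17,0.84,0.70,0.63
S18,0.82,0.71,0.61
S19,0.85,0.91,0.83
S20,0.78,0.72,0.61
S21,0.74,0.84,0.66
S22,0.80,0.80,0.67
S23,0.89,0.95,0.91
S24,0.95,0.96,0.94
S25,0.92,0.92,0.89
S26,0.87,0.79,0.71
S27,0.78,0.68,0.59
S28,0.87,0.84,0.76
S28,0.81,0.78,0.74
S30,0.70,0.71,0.57
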