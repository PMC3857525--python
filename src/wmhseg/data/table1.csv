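subject,rater1,rater2,semi_automated
S1,3.65,3.78,3.49
S2,26.38,26.43,26.95
S3,10.64,14.63,12.69
S4,5.38,5.25,4.65
S5,10.84,10.98,9.49
S6,7.97,6.73,7.72
S7,12.51,14.75,11.21
S8,7.54,7.75,7.28
S9,37.22,37.39,35.27
S10,10.52,12.57,10.71
S11,9.55,12.74,15.26
S12,27.53,33.27,25.83
S13,9.05,8.15,10.31
S14,14.32,16.92,17.64
S15,4.67,4.98,5.22
S16,20.87,22.53,19.69
S17,8.40,10.19,13.90
S18,29.22,37.54,43.35
S19,12.27,15.60,13.40
S20,6.09,8.67,9.35
S21,13.24,20.27,15.93
S22,43.11,63.30,62.49
S23,31.76,37.84,32.87
S24,7.99,8.42,7.51
S25,6.56,7.01,6.55
S26,19.12,22.67,26.73
S27,24.46,28.96,35.23
S28,9.02,11.27,11.89
S28,65.70,68.34,51.33
S30,6.62,5.98,5.02
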