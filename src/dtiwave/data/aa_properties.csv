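amino_acid,H,VSC,P1,P2,SASA,NCISC
A,0.62,27.5,8.1,0.046,1.181,0.007187
C,0.29,44.6,5.5,0.128,1.461,-0.03661
D,-0.9,40,13,0.105,1.587,-0.02382
E,-0.74,62,12.3,0.151,1.862,0.006802
F,1.19,115.5,5.2,0.29,2.228,0.037552
G,0.48,0,9,0,0.881,0.179052
H,-0.4,79,10.4,0.23,2.025,-0.01069
I,1.38,93.5,5.2,0.186,1.81,0.021631
K,-1.5,100,11.3,0.219,2.258,0.017708
L,1.06,93.5,4.9,0.186,1.931,0.051672
M,0.64,94.1,5.7,0.221,2.034,0.002683
N,-0.78,58.7,11.6,0.134,1.655,0.005392
P,0.12,41.9,8,0.131,1.468,0.239531
Q,-0.85,80.7,10.5,0.18,1.932,0.049211
R,-2.53,105,10.5,0.291,2.56,0.043587
S,-0.18,29.3,9.2,0.062,1.298,0.004627
T,-0.05,51.3,8.6,0.108,1.525,0.003352
V,1.08,71.5,5.9,0.14,1.645,0.057004
W,0.81,145.5,5.4,0.409,2.663,0.037977
Y,0.26,117.3,6.2,0.298,2.368,0.023599
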