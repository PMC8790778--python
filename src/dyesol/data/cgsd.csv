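solvent_smiles,et30,sa,sb,sdp,sp
O,63.1,1.062,0.025,0.997,0.681
CO,55.4,0.605,0.545,0.904,0.608
CCO,51.9,0.400,0.658,0.783,0.633
CC#N,45.6,0.044,0.286,0.974,0.645
CS(C)=O,45.1,0.072,0.647,1.000,0.830
CC(C)=O,42.2,0.000,0.475,0.907,0.651
ClCCl,40.7,0.040,0.178,0.769,0.761
C1CCOC1,37.4,0.000,0.591,0.634,0.714
ClC(Cl)Cl,39.1,0.047,0.071,0.614,0.783
Cc1ccccc1,33.9,0.000,0.128,0.284,0.782
c1ccccc1,34.3,0.000,0.124,0.270,0.793
CCCCCC,31.0,0.000,0.056,0.000,0.616
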