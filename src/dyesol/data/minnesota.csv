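solvent_smiles,n,alpha,beta,gamma,epsilon,phi,psi
O,1.3328,0.82,0.35,71.99,78.36,0.000,0.000
CO,1.3288,0.43,0.47,22.07,32.61,0.000,0.000
CCO,1.3611,0.37,0.48,21.97,24.85,0.000,0.000
CC#N,1.3442,0.07,0.32,28.66,35.69,0.000,0.000
CS(C)=O,1.4793,0.00,0.88,42.92,46.83,0.000,0.000
CC(C)=O,1.3588,0.04,0.49,23.46,20.49,0.000,0.000
ClCCl,1.4242,0.10,0.05,27.20,8.93,0.000,0.667
C1CCOC1,1.4050,0.00,0.48,26.50,7.43,0.000,0.000
ClC(Cl)Cl,1.4459,0.15,0.02,26.67,4.71,0.000,0.750
Cc1ccccc1,1.4961,0.00,0.14,27.93,2.37,0.857,0.000
c1ccccc1,1.5011,0.00,0.14,28.22,2.27,1.000,0.000
CCCCCC,1.3749,0.00,0.00,17.89,1.88,0.000,0.000
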