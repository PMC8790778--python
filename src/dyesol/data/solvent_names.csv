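name,smiles
water,O
h2o,O
methanol,CO
meoh,CO
ethanol,CCO
etoh,CCO
acetonitrile,CC#N
mecn,CC#N
acn,CC#N
dmso,CS(C)=O
dimethyl sulfoxide,CS(C)=O
acetone,CC(C)=O
dichloromethane,ClCCl
dcm,ClCCl
tetrahydrofuran,C1CCOC1
thf,C1CCOC1
chloroform,ClC(Cl)Cl
chcl3,ClC(Cl)Cl
toluene,Cc1ccccc1
benzene,c1ccccc1
hexane,CCCCCC
n-hexane,CCCCCC
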