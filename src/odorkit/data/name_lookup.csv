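name,smiles
2-phenylethyl acetate,CC(=O)OCCc1ccccc1
"acetic acid, 2-phenylethyl ester",CC(=O)OCCc1ccccc1
phenethyl acetate,CC(=O)OCCc1ccccc1
menthyl acetate,CC(=O)O[C@@H]1C[C@@H](C)CC[C@H]1C(C)C
2-pentylfuran,CCCCCc1ccco1
furfural,O=Cc1ccco1
geraniol,CC(C)=CCC/C(C)=C/CO
cis-geraniol,CC(C)=CCC/C(C)=C\CO
nerol,CC(C)=CCC/C(C)=C\CO
citronellol,CC(CCO)CCC=C(C)C
"butanoic acid, 2-methylbutyl ester",CCCC(=O)OCC(C)CC
2-methylbutyl butanoate,CCCC(=O)OCC(C)CC
phenethyl alcohol,OCCc1ccccc1
2-phenylethanol,OCCc1ccccc1
hexanal,CCCCCC=O
ethyl butanoate,CCCC(=O)OCC
ethyl acetate,CCOC(C)=O
acetic acid,CC(=O)O
ethanol,CCO
linalool,C=CC(C)(O)CCC=C(C)C
limonene,CC1=CCC(C(C)=C)CC1
benzaldehyde,O=Cc1ccccc1
vanillin,COc1cc(C=O)ccc1O
eugenol,C=CCc1ccc(O)c(OC)c1
hexyl acetate,CCCCCCOC(C)=O
isoamyl acetate,CC(C)CCOC(C)=O
gamma-decalactone,CCCCCCC1CCC(=O)O1
beta-ionone,CC1=C(/C=C/C(C)=O)C(C)(C)CCC1
1-octen-3-ol,C=CC(O)CCCCC
dimethyl sulfide,CSC
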