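compound,concentration_mg_L,n_detected,n_panelists,descriptors,intensity_mean,intensity_sd
2-phenylethyl acetate,0,0,20,None: 0,0.00,0.00
2-phenylethyl acetate,0.1,6,20,sweet: 3; floral: 2; alcoholic: 1; fruity: 1; rose: 1; woody: 1,0.47,0.77
2-phenylethyl acetate,1,18,20,floral: 10; cooling: 3; sweet: 3; minty: 2; rose: 2; alcoholic: 1; fermented: 1; fruity: 1; honey: 1; leafy: 1; sour: 1; woody: 1,1.82,0.88
2-phenylethyl acetate,10,20,20,floral: 14; sweet: 5; alcoholic: 1; cooling: 1; fruity: 1; honey: 1; minty: 1; rose: 1; woody: 1,2.49,0.81
2-phenylethyl acetate,100,20,20,floral: 15; sweet: 7; fruity: 4; rose: 4; alcoholic: 1; honey: 1; minty: 1,3.77,0.53
2-phenylethyl acetate,1000,20,20,floral: 15; sweet: 7; fruity: 4; rose: 3; minty: 2; fermented: 1; honey: 1; pungent: 1,4.55,0.60
menthyl acetate,0,0,20,None: 0,0.00,0.00
menthyl acetate,0.01,2,20,grassy: 1; sweet: 1,0.10,0.31
menthyl acetate,0.1,5,20,grassy: 3; cooling: 1; honey: 1; minty: 1; other: 1,0.30,0.55
menthyl acetate,1,10,20,grassy: 5; leaf: 2; other: 2; cooling: 1; honey: 1; leafy: 1; minty: 1,0.72,0.87
menthyl acetate,10,18,20,grassy: 9; leaf: 8; fruity: 5; cooling: 2; honey: 1,2.06,0.96
menthyl acetate,100,20,20,grassy: 17; leaf: 13; cooling: 9; other: 4; floral: 1; honey: 1; sour: 1,3.25,0.87
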