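label,name,kappa,rho,c,w,emissivity
1,muscle,0.49,1090.0,3421.0,0.00050,0.95
2,fat,0.21,911.0,2348.0,0.00010,0.95
3,bone,0.75,1908.0,1313.0,0.00005,0.95
4,viscera,0.52,1050.0,3600.0,0.00200,0.95
5,lung,0.39,394.0,3886.0,0.00300,0.95
9,wet_soil,2.0,1900.0,2200.0,0.0,0.95
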