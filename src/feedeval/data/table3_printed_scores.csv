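score,category,isopod,krill,fish
AAS,Ile,0.30,0.60,0.73
AAS,Leu,0.61,0.55,0.78
AAS,Lys,0.62,0.68,0.99
AAS,Thr,0.47,0.48,0.75
AAS,Val,0.79,0.48,0.69
AAS,Trp,0.64,0.92,0.65
AAS,Met+Cys,0.18,0.80,0.88
AAS,Phe+Tyr,0.59,0.67,0.86
CS,Ile,0.22,0.46,0.55
CS,Leu,0.50,0.46,0.64
CS,Lys,0.48,0.53,0.76
CS,Thr,0.40,0.41,0.64
CS,Val,0.59,0.36,0.53
CS,Trp,0.36,0.52,0.37
CS,Met+Cys,0.10,0.45,0.50
CS,Phe+Tyr,0.40,0.45,0.58
EAAI,EAAI,34.13,45.16,55.93
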