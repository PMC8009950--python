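substrate,analyte,mean,ci95,letter,essential,flavor,aggregate
isopod,Asp,4.16,0.07,a,0,1,0
isopod,Thr,1.86,0.05,a,1,0,0
isopod,Ser,1.38,0.12,a,0,0,0
isopod,Glu,4.66,0.05,a,0,1,0
isopod,Gly,6.96,0.05,c,0,1,0
isopod,Ala,2.11,0.07,a,0,1,0
isopod,Val,3.90,0.10,c,1,0,0
isopod,Met,0.54,0.02,a,1,0,0
isopod,Ile,1.19,0.05,a,1,0,0
isopod,Leu,4.26,0.05,b,1,0,0
isopod,Tyr,1.76,0.02,b,1,0,0
isopod,Phe,1.84,0.05,a,1,0,0
isopod,Lys,3.36,0.05,a,1,0,0
isopod,His,0.99,0.10,a,0,0,0
isopod,Arg,4.24,0.01,b,0,0,0
isopod,Pro,2.37,0.07,b,0,0,0
isopod,Cys,0.09,0.07,a,1,0,0
isopod,Trp,0.61,0.02,a,1,0,0
isopod,Tau,9.45,0.20,c,0,1,0
isopod,SumAA,55.61,1.91,b,0,0,1
isopod,SumEAA,19.57,1.44,a,0,0,1
isopod,SumNEAA,36.73,1.41,b,0,0,1
isopod,SumFAA,27.45,1.17,b,0,0,1
isopod,SumEAA/SumAA,35.21,1.14,a,0,0,1
isopod,SumEAA/SumNEAA,53.29,2.78,a,0,0,1
isopod,SumFAA/SumAA,49.37,1.19,a,0,0,1
krill,Asp,4.97,0.10,b,0,1,0
krill,Thr,1.92,0.07,b,1,0,0
krill,Ser,2.02,0.05,b,0,0,0
krill,Glu,7.06,0.05,b,0,1,0
krill,Gly,2.04,0.05,a,0,1,0
krill,Ala,2.56,0.12,b,0,1,0
krill,Val,2.38,0.07,a,1,0,0
krill,Met,1.46,0.05,b,1,0,0
krill,Ile,2.41,0.05,b,1,0,0
krill,Leu,3.90,0.02,a,1,0,0
krill,Tyr,1.68,0.01,a,1,0,0
krill,Phe,2.39,0.10,b,1,0,0
krill,Lys,3.72,0.02,b,1,0,0
krill,His,2.01,0.02,c,0,0,0
krill,Arg,2.94,0.05,a,0,0,0
krill,Pro,1.68,0.10,a,0,0,0
krill,Cys,1.34,0.05,b,1,0,0
krill,Trp,0.88,0.10,b,1,0,0
krill,Tau,2.93,0.10,b,0,1,0
krill,SumAA,50.11,0.92,a,0,0,1
krill,SumEAA,20.73,1.69,b,0,0,1
krill,SumNEAA,29.41,0.45,a,0,0,1
krill,SumFAA,19.54,2.24,a,0,0,1
krill,SumEAA/SumAA,41.38,2.51,b,0,0,1
krill,SumEAA/SumNEAA,70.52,5.14,b,0,0,1
krill,SumFAA/SumAA,38.98,4.37,b,0,0,1
fish,Asp,6.68,0.05,c,0,1,0
fish,Thr,2.98,0.07,c,1,0,0
fish,Ser,3.18,0.05,c,0,0,0
fish,Glu,9.62,0.01,c,0,1,0
fish,Gly,4.43,0.07,b,0,1,0
fish,Ala,4.35,0.07,c,0,1,0
fish,Val,3.44,0.05,b,1,0,0
fish,Met,1.72,0.10,c,1,0,0
fish,Ile,2.91,0.10,c,1,0,0
fish,Leu,5.50,0.07,c,1,0,0
fish,Tyr,2.40,0.02,c,1,0,0
fish,Phe,2.84,0.02,c,1,0,0
fish,Lys,5.39,0.10,c,1,0,0
fish,His,1.62,0.05,b,0,0,0
fish,Arg,4.50,0.07,c,0,0,0
fish,Pro,3.15,0.01,c,0,0,0
fish,Cys,1.37,0.05,b,1,0,0
fish,Trp,0.62,0.02,a,1,0,0
fish,Tau,2.04,0.12,a,0,1,0
fish,SumAA,68.55,0.75,c,0,0,1
fish,SumEAA,27.74,1.04,c,0,0,1
fish,SumNEAA,40.63,2.66,c,0,0,1
fish,SumFAA,27.28,0.27,b,0,0,1
fish,SumEAA/SumAA,40.47,1.24,b,0,0,1
fish,SumEAA/SumNEAA,68.34,2.01,b,0,0,1
fish,SumFAA/SumAA,39.80,0.45,b,0,0,1
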