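substrate,analyte,value,ci95,letter,censor,aggregate
isopod,C14:0,1.95,0.10,a,observed,0
isopod,C16:0,27.33,0.02,a,observed,0
isopod,C18:0,4.39,0.05,c,observed,0
isopod,SumSFA,33.66,4.99,b,observed,1
isopod,C16:1,11.22,0.07,c,observed,0
isopod,C18:1 n9,7.48,0.02,a,observed,0
isopod,C24:1 n9,0.57,0.05,,observed,0
isopod,SumMUFA,19.28,3.03,a,observed,1
isopod,C18:2 n6 c,10.11,0.10,c,observed,0
isopod,C18:3 n6,0.33,0.02,c,observed,0
isopod,C18:3 n3,3.41,0.05,c,observed,0
isopod,C20:2 n6,0.5,0.05,a,observed,0
isopod,C20:3 n6,0.29,0.05,a,observed,0
isopod,C20:3 n3,0.31,0.05,,observed,0
isopod,EPA C20:5 n3,6.54,0.02,a,observed,0
isopod,DPA C22:5 n3,0.62,0.05,b,observed,0
isopod,DHA C22:6 n3,1.27,0.07,a,observed,0
isopod,EPA+DPA+DHA,8.40,0.67,a,observed,1
isopod,Sum n-3 PUFA,12.12,0.75,a,observed,1
isopod,Sum n-6 PUFA,11.50,1.74,b,observed,1
isopod,SumPUFA,23.61,2.50,a,observed,1
isopod,Sum n-3/n-6,1.06,0.10,a,observed,1
krill,C14:0,8.90,0.05,c,observed,0
krill,C16:0,22.89,0.02,b,observed,0
krill,C17:0,0.26,0.07,,observed,0
krill,C18:0,1.20,0.05,a,observed,0
krill,SumSFA,33.13,3.00,b,observed,1
krill,C16:1,6.93,0.05,a,observed,0
krill,C18:1 n9,18.0,0.05,c,observed,0
krill,C20:1 n9,1.64,0.05,b,observed,0
krill,SumMUFA,26.57,1.14,b,observed,1
krill,C18:2 n6 c,3.10,0.12,b,observed,0
krill,C18:3 n6,0.40,0.02,b,observed,0
krill,C18:3 n3,0.94,0.05,b,observed,0
krill,C20:2 n6,4.21,0.10,c,observed,0
krill,C20:3 n6,0.32,0.07,a,observed,0
krill,C20:4 n6,0.51,0.15,,observed,0
krill,EPA C20:5 n3,18.30,0.05,c,observed,0
krill,DPA C22:5 n3,0.44,0.07,a,observed,0
krill,DHA C22:6 n3,12.30,0.05,b,observed,0
krill,EPA+DPA+DHA,31.01,3.88,c,observed,1
krill,Sum n-3 PUFA,31.96,3.90,b,observed,1
krill,Sum n-6 PUFA,8.55,0.47,a,observed,1
krill,SumPUFA,40.50,4.37,b,observed,1
krill,Sum n-3/n-6,3.74,0.25,b,observed,1
fish,C14:0,5.90,0.10,b,observed,0
fish,C16:0,17.32,0.05,c,observed,0
fish,C17:0,0.58,0.05,,observed,0
fish,C18:0,2.78,0.02,b,observed,0
fish,SumSFA,26.88,3.16,a,observed,1
fish,C16:1,8.31,0.07,b,observed,0
fish,C17:1,0.32,0.05,,observed,0
fish,C18:1 n9,15.29,0.02,b,observed,0
fish,C20:1 n9,0.85,0.07,a,observed,0
fish,C22:1 n9,1.19,0.05,,observed,0
fish,C24:1 n9,0.81,0.12,,observed,0
fish,SumMUFA,26.61,1.86,b,observed,1
fish,C18:2 n6 c,1.79,0.05,a,observed,0
fish,C18:3 n6,0.04,0.01,a,observed,0
fish,C18:3 n3,1.05,0.02,a,observed,0
fish,C20:2 n6,2.06,0.07,b,observed,0
fish,C20:3 n6,12.94,0.10,b,observed,0
fish,C20:3 n3,0.31,0.02,,observed,0
fish,C20:4 n6,0.70,0.05,,observed,0
fish,EPA C20:5 n3,14.70,0.05,b,observed,0
fish,DPA C22:5 n3,1.13,0.05,c,observed,0
fish,DHA C22:6 n3,12.95,0.15,c,observed,0
fish,EPA+DPA+DHA,28.70,2.71,b,observed,1
fish,Sum n-3 PUFA,30.06,2.71,b,observed,1
fish,Sum n-6 PUFA,17.18,3.97,c,observed,1
fish,SumPUFA,47.27,6.68,c,observed,1
fish,Sum n-3/n-6,1.76,0.25,c,observed,1
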