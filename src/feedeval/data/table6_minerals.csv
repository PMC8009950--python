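substrate,analyte,value,ci95,letter,unit,censor
isopod,Ca,90283,1536.34,c,mg/kg,observed
isopod,K,5403.4,148.76,c,mg/kg,observed
isopod,Na,8117.13,315.41,b,mg/kg,observed
isopod,Mg,4862.67,100.74,c,mg/kg,observed
isopod,Cu,31.00,4.97,b,mg/kg,observed
isopod,Fe,882.67,18.31,c,mg/kg,observed
isopod,Zn,62.95,6.86,b,mg/kg,observed
isopod,Cr,2,0.35,,mg/kg,observed
isopod,Se,2.69,0.30,c,mg/kg,observed
isopod,Mn,60.67,6.26,a,mg/kg,observed
isopod,total_P,0.43,0.05,c,%,observed
krill,Ca,21536.04,3688.32,b,mg/kg,observed
krill,K,2378.68,340.11,a,mg/kg,observed
krill,Na,10592.23,1528.86,c,mg/kg,observed
krill,Mg,4517.53,508.37,b,mg/kg,observed
krill,Cu,70.76,18.93,c,mg/kg,observed
krill,Fe,84.27,25.04,b,mg/kg,observed
krill,Zn,52.04,7.08,a,mg/kg,observed
krill,Se,1.54,0.32,b,mg/kg,observed
krill,Mn,2.6,0.50,c,mg/kg,observed
krill,total_P,1.42,0.01,a,%,observed
fish,Ca,18575.06,2630.42,a,mg/kg,observed
fish,K,3352.11,294.32,b,mg/kg,observed
fish,Na,4033.63,1039.12,a,mg/kg,observed
fish,Mg,1256.98,255.49,a,mg/kg,observed
fish,Cu,4.74,18.93,a,mg/kg,observed
fish,Fe,22.10,2.81,a,mg/kg,observed
fish,Zn,74.40,10.48,c,mg/kg,observed
fish,Se,0.4,0.01,a,mg/kg,observed
fish,Mn,25,4.97,b,mg/kg,observed
fish,total_P,1.15,0.19,b,%,observed
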