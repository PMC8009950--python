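substrate,analyte,value,ci95,letter,unit,censor
isopod,VA,0.05,,,mg/100g,below_limit
isopod,VD3,2,,,ug/100g,below_limit
isopod,VK1,64.0,7.45,,ug/100g,observed
isopod,VE,9.32,0.35,c,mg/100g,observed
isopod,VB1,0,,,mg/100g,not_detected
isopod,VB2,1.68,0.00,b,mg/100g,observed
isopod,VB3,2.83,0.70,b,mg/100g,observed
isopod,VB5,2.43,1.29,,mg/100g,observed
isopod,VB6,0,,,mg/kg,not_detected
isopod,VB12,0,,,mg/kg,not_detected
isopod,folic_acid,0,,,mg/kg,not_detected
isopod,VC,1,,,mg/100g,below_limit
krill,VA,0.05,,,mg/100g,below_limit
krill,VD3,2,,,ug/100g,below_limit
krill,VK1,1,,,ug/100g,below_limit
krill,VE,2.53,0.07,b,mg/100g,observed
krill,VB1,0.04,0.01,,mg/100g,observed
krill,VB2,0.12,0.02,a,mg/100g,observed
krill,VB3,1.41,1.02,a,mg/100g,observed
krill,VB5,0,,,mg/100g,not_detected
krill,VB6,0,,,mg/kg,not_detected
krill,VB12,0.849,0.45,,mg/kg,observed
krill,folic_acid,0,,,mg/kg,not_detected
krill,VC,1,,,mg/100g,below_limit
fish,VA,0.19,0.12,,mg/100g,observed
fish,VD3,2,,,ug/100g,below_limit
fish,VK1,1,,,ug/100g,below_limit
fish,VE,0.82,0.02,a,mg/100g,observed
fish,VB1,0,,,mg/100g,not_detected
fish,VB2,0.12,0.21,a,mg/100g,observed
fish,VB3,0,,,mg/100g,not_detected
fish,VB5,0,,,mg/100g,not_detected
fish,VB6,0,,,mg/kg,not_detected
fish,VB12,0,,,mg/kg,not_detected
fish,folic_acid,0,,,mg/kg,not_detected
fish,VC,1,,,mg/100g,below_limit
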