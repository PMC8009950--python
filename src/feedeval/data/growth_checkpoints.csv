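dah,mean_mg,ci95
0,0.24,0.005
15,0.85,0.02
45,6.37,0.04
55,12.69,0.01
60,16.37,0.41
70,31.06,1.06
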