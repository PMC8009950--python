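pattern,category,mg_per_gN
fao_who,Ile,250
fao_who,Leu,440
fao_who,Lys,340
fao_who,Thr,250
fao_who,Val,310
fao_who,Trp,60
fao_who,Met+Cys,220
fao_who,Phe+Tyr,380
egg,Ile,331
egg,Leu,534
egg,Lys,441
egg,Thr,292
egg,Val,410
egg,Trp,106
egg,Met+Cys,386
egg,Phe+Tyr,565
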