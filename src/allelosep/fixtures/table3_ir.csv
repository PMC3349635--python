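donor,receiver,trait,tb,tb_se,ae,ae_se
PI,BYG,RL,57.79,0.24,40.88,0.15
PI,BYG,PH,49.51,0.34,36.22,0.25
PI,BYG,DW,43.42,0.002,38.98,0.001
LE,BYG,RL,30.05,0.11,8.36,0.14
LE,BYG,PH,18.33,0.39,8.39,0.46
LE,BYG,DW,21.71,0.004,11.02,0.003
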