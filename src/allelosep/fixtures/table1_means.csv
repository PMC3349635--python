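species,arm,partner_species,trait,mean,se,n
BYG,monoculture,none,RL,7.32,0.26,3
BYG,monoculture,none,PH,19.37,0.56,3
BYG,monoculture,none,DW,0.152,0.005,3
BYG,mixed,LE,RL,5.01,0.15,3
BYG,mixed,LE,PH,15.46,0.25,3
BYG,mixed,LE,DW,0.115,0.003,3
BYG,mixed,PI,RL,2.66,0.17,3
BYG,mixed,PI,PH,8.82,0.29,3
BYG,mixed,PI,DW,0.0810,0.003,3
PI,monoculture,none,RL,8.73,0.18,3
PI,monoculture,none,PH,36.24,0.56,3
PI,monoculture,none,DW,0.412,0.005,3
PI,mixed,BYG,RL,10.26,0.09,3
PI,mixed,BYG,PH,44.35,0.83,3
PI,mixed,BYG,DW,0.472,0.003,3
LE,monoculture,none,RL,9.21,0.13,3
LE,monoculture,none,PH,38.19,0.49,3
LE,monoculture,none,DW,0.446,0.004,3
LE,mixed,BYG,RL,8.71,0.11,3
LE,mixed,BYG,PH,35.22,0.51,3
LE,mixed,BYG,DW,0.403,0.006,3
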