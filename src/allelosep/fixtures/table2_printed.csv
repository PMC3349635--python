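focal,partner,trait,index,printed
PI,BYG,RL,RCI,-0.1753
PI,BYG,PH,RCI,-0.2238
PI,BYG,DW,RCI,-0.1456
LE,BYG,RL,RCI,0.05429
LE,BYG,PH,RCI,0.07777
LE,BYG,DW,RCI,0.09641
BYG,PI,RL,RCI,0.6366
BYG,PI,PH,RCI,0.5447
BYG,PI,DW,RCI,0.4671
BYG,LE,RL,RCI,0.3156
BYG,LE,PH,RCI,0.2019
BYG,LE,DW,RCI,0.2434
PI,BYG,RL,CR,3.2342
PI,BYG,PH,CR,2.6876
PI,BYG,DW,CR,2.1498
LE,BYG,RL,CR,1.3818
LE,BYG,PH,CR,1.1555
LE,BYG,DW,CR,1.1943
BYG,PI,RL,CR,0.3092
BYG,PI,PH,CR,0.3721
BYG,PI,DW,CR,0.4652
BYG,LE,RL,CR,0.7237
BYG,LE,PH,CR,0.8654
BYG,LE,DW,CR,0.8373
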