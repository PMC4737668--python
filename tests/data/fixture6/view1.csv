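subject_id,f0,f1
s000,-0.206924186,-0.118929526
s001,-0.949680389,2.71370627
s002,0.00132246989,1.76430989
s003,-0.824069147,-0.012935503
s004,-1.84812918,-0.559643844
s005,0.806978213,-1.42852051
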