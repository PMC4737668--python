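r0,r1,r2,r3,r4,r5,r6,r7,r8,r9,r10,r11
0,1,0,0,0,0,0,0,1,0,0,0
1,0,0,1,1,0,0,1,0,0,0,0
0,0,0,0,0,1,0,0,0,0,0,1
0,1,0,0,0,1,1,0,0,0,0,0
0,1,0,0,0,0,0,1,0,0,0,0
0,0,1,1,0,0,1,0,1,0,0,1
0,0,0,1,0,1,0,0,0,1,0,0
0,1,0,0,1,0,0,0,0,0,0,1
1,0,0,0,0,1,0,0,0,0,1,0
0,0,0,0,0,0,1,0,0,0,0,0
0,0,0,0,0,0,0,0,1,0,0,0
0,0,1,0,0,1,0,1,0,0,0,0
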