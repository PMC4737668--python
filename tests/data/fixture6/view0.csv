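subject_id,f0,f1,f2
s000,0.0974397307,0.505099986,1.29038552
s001,-1.44445736,-0.495454939,0.464009978
s002,0.680769921,-0.0883993158,1.31785437
s003,-0.0782801958,-1.50205727,-1.21943891
s004,0.516795926,0.175156322,-2.18773637
s005,1.05903717,0.309351896,1.05466785
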