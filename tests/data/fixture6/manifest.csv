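subject_id,path,label
s000,matrices/s000.csv,1
s001,matrices/s001.csv,1
s002,matrices/s002.csv,1
s003,matrices/s003.csv,-1
s004,matrices/s004.csv,-1
s005,matrices/s005.csv,-1
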