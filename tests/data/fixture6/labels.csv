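subject_id,label
s000,1
s001,1
s002,1
s003,-1
s004,-1
s005,-1
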