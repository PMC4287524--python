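T1520\F1534,FF,FC,CC
TT,28,22,105
TI,0,8,37
II,0,0,3
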