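name,recognition,cut_offset_top,cut_offset_bottom
BsaBI,GATNNNNATC,5,5
SsiI,CCGC,1,3
EcoRI,GAATTC,1,5
HindIII,AAGCTT,1,5
TaqI,TCGA,1,3
AluI,AGCT,2,2
HinfI,GANTC,1,4
DdeI,CTNAG,1,4
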