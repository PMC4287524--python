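population,locus,n_wild_hom,n_het,n_mut_hom
South Delhi I,F1534,118,195,214
South Delhi II,F1534,35,128,158
West Delhi,F1534,139,112,81
Pooled,F1534,292,435,453
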