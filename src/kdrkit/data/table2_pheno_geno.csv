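insecticide,locus,phenotype,n_wild_hom,n_het,n_mut_hom
DDT,F1534,dead,38,26,4
DDT,F1534,alive,41,72,113
deltamethrin,F1534,dead,51,55,46
deltamethrin,F1534,alive,11,19,26
permethrin,F1534,dead,50,59,99
permethrin,F1534,alive,9,18,31
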