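>synthetic-pre-miR1448 synthetic reference hairpin around published mature miR1448
GUAAUUGUUACAAUUUUUACUUUCCAACGCCUCCCAUACAACUAUGGUAUGGGAGGCGUU
GGAAAGUAAAAAUUGUAACAAUUAC
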