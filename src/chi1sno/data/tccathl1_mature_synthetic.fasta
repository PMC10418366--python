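>tccathl1_mature_synthetic | SYNTHETIC stand-in for the mature Tribolium castaneum cathepsin L chain (not the UniProt sequence); numbering_offset=115; ionizable composition D14 E10 H2 K4 R5; catalytic triad C138/H275/N295, V277, A251
PRIFAYGGDLMLVELDDSFTLACGSNHGNVACGSTKQDYAGPGKVRVGPKPAAMGRCRLQ
PSTEDGSFFLVGFALPFGPLDQPLQLADYRSVLLVSQEATADSLDYLANLGFTEPLGIKL
ELILLVASGGIEGVDAQMNGGYINPCLQAYSQNTFESWEHSVACFTDAWYVPGPNGFLDN
TEYALNSEAFQQDGLAPFIDGTCPLTIPSIIGPCGGGGSG
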