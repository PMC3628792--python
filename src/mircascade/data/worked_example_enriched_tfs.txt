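PPARG
RXRA
NFE2L2
SREBF1
NFATC4
EGR1
GATA2
MYCN
NKX2-5
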