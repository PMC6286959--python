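TP53
CDKN1A
GADD45A
MDM2
BAX
RRM2B
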