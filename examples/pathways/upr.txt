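ATF4
ATF6
XBP1
HSPA5
EIF2S2
SLC7A11
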