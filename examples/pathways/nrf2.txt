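NFE2L2
HMOX1
NQO1
GCLM
TXNRD1
SRXN1
GCLC
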