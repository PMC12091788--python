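source,target
n0000,n0004
n0000,n0009
n0001,n0005
n0001,n0008
n0002,n0006
n0002,n0009
n0003,n0004
n0005,n0007
n0005,n0008
n0006,n0007
n0007,n0009
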