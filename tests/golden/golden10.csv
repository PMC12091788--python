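source,target,weight
n0000,n0003,2.609085507013643
n0000,n0004,5.662739192960316
n0000,n0006,6.690115178343425
n0000,n0008,1.0961594792847267
n0000,n0009,7.901879709514531
n0001,n0002,4.3828017147844065
n0001,n0005,7.9206653280419985
n0001,n0008,9.546513401312
n0002,n0003,7.314261869892488
n0002,n0004,1.1416453050679276
n0002,n0006,7.825897050468459
n0002,n0007,5.834505630149557
n0002,n0009,9.483566344478099
n0003,n0004,7.764783345287502
n0003,n0006,5.6104538020959165
n0003,n0009,2.276782605768856
n0005,n0007,9.65111026229525
n0005,n0008,7.804890589791034
n0006,n0007,7.032155478909312
n0007,n0008,2.053409166294434
n0007,n0009,9.085777696411531
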