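# consecutive protein-protein interaction chain
AT3G17609	AT5G11260
AT5G11260	AT1G56650
AT1G56650	AT5G41315
AT5G41315	AT1G63650
AT1G63650	AT5G35550
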