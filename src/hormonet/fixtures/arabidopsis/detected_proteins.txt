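# root proteome detected loci
AT1G06000
AT1G71930
AT1G78380
AT2G30860
AT2G30870
AT2G47730
AT3G55360
AT3G63410
AT4G32410
AT5G05170
AT5G13930
AT5G19440
AT5G43940
AT5G64740
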