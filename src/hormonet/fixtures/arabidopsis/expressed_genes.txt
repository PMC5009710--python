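# root-stele expressed loci (enzyme-encoding genes and TFs)
AT1G01480
AT1G02400
AT1G05010
AT1G06000
AT1G12610
AT1G14130
AT1G14920
AT1G19850
AT1G32640
AT1G45249
AT1G52890
AT1G53910
AT1G62380
AT1G62960
AT1G67560
AT1G70560
AT1G73730
AT1G73880
AT1G75080
AT1G77330
AT1G78270
AT1G78380
AT2G01570
AT2G03220
AT2G27150
AT2G27690
AT2G28080
AT2G30140
AT2G30860
AT2G30870
AT2G46370
AT2G47190
AT2G47460
AT2G47730
AT3G01470
AT3G16770
AT3G18990
AT3G19010
AT3G20770
AT3G21750
AT3G22400
AT3G49630
AT3G50210
AT3G50410
AT3G50660
AT3G53160
AT3G55360
AT3G61850
AT3G63410
AT4G11280
AT4G15550
AT4G16770
AT4G25470
AT4G25490
AT4G27260
AT4G32410
AT4G34135
AT4G34138
AT4G34990
AT4G36380
AT4G36930
AT4G37770
AT5G04660
AT5G05170
AT5G08640
AT5G11260
AT5G13930
AT5G17050
AT5G19440
AT5G20730
AT5G20960
AT5G38970
AT5G40390
AT5G43940
AT5G48000
AT5G51690
AT5G54160
AT5G54510
AT5G62000
AT5G64740
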