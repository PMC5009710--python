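# TF locus -> target locus; full bipartite expansion per control unit
AT2G20180	AT1G80340
AT2G20180	AT4G25420
AT2G20180	AT1G47990
AT2G20180	AT1G15550
AT2G20180	AT1G78390
AT3G26790	AT1G80340
AT3G26790	AT4G25420
AT3G26790	AT1G47990
AT3G26790	AT1G15550
AT3G26790	AT1G78390
AT2G01570	AT1G80340
AT2G01570	AT4G25420
AT2G01570	AT1G47990
AT2G01570	AT1G15550
AT2G01570	AT1G78390
AT4G08150	AT1G80340
AT4G08150	AT4G25420
AT4G08150	AT1G47990
AT4G08150	AT1G15550
AT4G08150	AT1G78390
AT1G62360	AT1G80340
AT1G62360	AT4G25420
AT1G62360	AT1G47990
AT1G62360	AT1G15550
AT1G62360	AT1G78390
AT4G18960	AT1G80340
AT4G18960	AT4G25420
AT4G18960	AT1G47990
AT4G18960	AT1G15550
AT4G18960	AT1G78390
AT3G61850	AT1G80340
AT3G61850	AT4G25420
AT3G61850	AT1G47990
AT3G61850	AT1G15550
AT3G61850	AT1G78390
AT4G25490	AT1G80340
AT4G25490	AT4G25420
AT4G25490	AT1G47990
AT4G25490	AT1G15550
AT4G25490	AT1G78390
AT4G36930	AT1G80340
AT4G36930	AT4G25420
AT4G36930	AT1G47990
AT4G36930	AT1G15550
AT4G36930	AT1G78390
AT1G28300	AT1G80340
AT1G28300	AT4G25420
AT1G28300	AT1G47990
AT1G28300	AT1G15550
AT1G28300	AT1G78390
AT3G61890	AT1G80340
AT3G61890	AT4G25420
AT3G61890	AT1G47990
AT3G61890	AT1G15550
AT3G61890	AT1G78390
AT1G14920	AT1G80340
AT1G14920	AT4G25420
AT1G14920	AT1G47990
AT1G14920	AT1G15550
AT1G14920	AT1G78390
AT2G20180	AT4G27260
AT2G20180	AT1G28130
AT5G37020	AT4G27260
AT5G37020	AT1G28130
AT5G37020	AT1G78390
AT3G51060	AT4G27260
AT3G51060	AT1G28130
AT3G51060	AT1G78390
AT1G77850	AT4G27260
AT1G77850	AT1G28130
AT1G77850	AT1G78390
AT5G20730	AT4G27260
AT5G20730	AT1G28130
AT5G20730	AT1G78390
AT1G67260	AT3G50660
AT1G67260	AT1G78390
AT2G20180	AT3G50660
AT1G75080	AT3G50660
AT1G75080	AT1G78390
AT1G19850	AT4G37770
AT1G19850	AT1G80340
AT3G59060	AT4G37770
AT3G59060	AT1G80340
AT5G62000	AT4G37770
AT5G62000	AT1G80340
AT1G28300	AT4G37770
AT5G01900	AT3G45140
AT5G01900	AT2G24850
AT2G24570	AT3G45140
AT2G24570	AT2G24850
AT1G52890	AT3G45140
AT1G52890	AT2G24850
AT1G32640	AT3G45140
AT1G32640	AT2G24850
AT3G15500	AT3G45140
AT3G15500	AT2G24850
AT4G31550	AT3G45140
AT4G31550	AT2G24850
AT1G27730	AT1G17420
AT1G74930	AT1G17420
AT1G32640	AT1G17420
AT1G62300	AT1G17420
AT2G03340	AT1G17420
AT1G45249	AT1G77120
AT1G35515	AT1G77120
AT2G47190	AT1G77120
AT4G25470	AT1G77120
AT1G53910	AT1G77120
AT1G32640	AT1G77120
AT5G35550	AT4G22880
AT5G35550	AT5G13930
AT5G35550	AT5G17050
AT5G13930	AT4G22880
AT5G13930	AT5G13930
AT5G13930	AT5G17050
AT4G38620	AT4G22880
AT4G38620	AT5G13930
AT4G38620	AT5G17050
AT2G47460	AT4G22880
AT2G47460	AT5G13930
AT2G47460	AT5G17050
AT4G34990	AT4G22880
AT4G34990	AT5G13930
AT4G34990	AT5G17050
AT1G02340	AT4G22880
AT1G02340	AT5G13930
AT1G02340	AT5G17050
AT5G11260	AT4G22880
AT5G11260	AT5G13930
AT5G11260	AT5G17050
AT1G09530	AT4G22880
AT1G09530	AT5G13930
AT1G09530	AT5G17050
AT2G43010	AT4G22880
AT2G43010	AT5G13930
AT2G43010	AT5G17050
AT3G17609	AT4G22880
AT3G17609	AT5G13930
AT3G17609	AT5G17050
AT1G63650	AT4G22880
AT1G63650	AT5G13930
AT1G63650	AT5G17050
AT5G41315	AT4G22880
AT5G41315	AT5G13930
AT5G41315	AT5G17050
AT1G56650	AT4G22880
AT1G56650	AT5G13930
AT1G56650	AT5G17050
AT3G28910	AT1G74710
AT3G28910	AT2G19590
AT3G20770	AT1G74710
AT3G20770	AT2G19590
AT2G27050	AT1G74710
AT2G27050	AT2G19590
AT1G10170	AT1G74710
AT1G10170	AT2G19590
AT3G01470	AT1G74710
AT3G01470	AT2G19590
AT3G50410	AT2G47730
AT3G16770	AT2G47730
AT1G69120	AT2G47730
AT5G60890	AT2G20610
AT5G61420	AT2G20610
AT3G13890	AT5G17420
AT1G71930	AT5G17420
AT5G07690	AT1G16400
AT1G73730	AT1G16400
AT1G16490	AT5G54160
AT1G79180	AT5G54160
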