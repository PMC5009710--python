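# Curated Arabidopsis phytohormone crosstalk fixture.
# Transcribed from published pathway, regulation and expression knowledge
# for the eight major phytohormones; identifiers prefixed PLACEHOLDER-,
# ROUTE-LINKER- or MARKER- are synthetic fixture scaffolding that stands in
# for entities the curated source does not name.
# AT2G36800 (EC 2.4.1.203) is a synthetic stand-in locus.
UNIQUE-ID - 1.3.1.-
COMMON-NAME - oxidoreductase (CH-CH donor family)
GENE - AT3G55360
//
UNIQUE-ID - 1.14.13.-
COMMON-NAME - oxidoreductase (NADPH monooxygenase family)
GENE - AT2G27690
GENE - AT5G04660
GENE - AT4G36380
GENE - AT5G38970
GENE - AT5G48000
GENE - AT3G50660
GENE - AT1G16400
//
UNIQUE-ID - 2.4.1.-
COMMON-NAME - hexosyltransferase family
GENE - AT3G53160
GENE - AT3G21750
GENE - AT4G34138
GENE - AT1G73880
GENE - AT4G34135
GENE - AT1G78270
GENE - AT1G06000
GENE - AT2G30140
GENE - AT5G40390
GENE - AT2G28080
GENE - AT5G17050
//
UNIQUE-ID - 2.4.1.203
COMMON-NAME - trans-zeatin O-beta-D-glucosyltransferase
GENE - AT2G36800
//
UNIQUE-ID - 1.14.11.23
COMMON-NAME - flavonol synthase
GENE - AT3G50210
GENE - AT3G49630
GENE - AT3G19010
GENE - AT4G16770
GENE - AT4G25420
GENE - AT4G22880
GENE - AT5G08640
//
UNIQUE-ID - 2.1.1.-
COMMON-NAME - methyltransferase family
GENE - AT3G63410
GENE - AT5G54160
//
UNIQUE-ID - 1.14.11.-
COMMON-NAME - oxidoreductase (2-oxoglutarate dioxygenase family)
GENE - AT1G14130
GENE - AT1G80340
GENE - AT1G47990
GENE - AT1G15550
GENE - AT1G02400
//
UNIQUE-ID - 1.2.3.7
COMMON-NAME - indole-3-acetaldehyde oxidase
GENE - AT2G27150
//
UNIQUE-ID - 2.4.1.121
COMMON-NAME - indole-3-acetate beta-glucosyltransferase
GENE - AT4G15550
//
UNIQUE-ID - 6.3.-.-
COMMON-NAME - ligase (amide-bond family, GH3)
GENE - AT2G46370
GENE - AT4G27260
GENE - AT1G28130
GENE - AT5G54510
//
UNIQUE-ID - 2.6.1.57
COMMON-NAME - aromatic-amino-acid transaminase
GENE - AT1G70560
GENE - AT1G62960
//
UNIQUE-ID - 4.4.1.14
COMMON-NAME - 1-aminocyclopropane-1-carboxylate synthase
GENE - AT5G51690
GENE - AT1G62960
GENE - AT4G37770
GENE - AT4G11280
GENE - AT1G01480
//
UNIQUE-ID - 1.14.17.4
COMMON-NAME - aminocyclopropanecarboxylate oxidase
GENE - AT1G05010
GENE - AT1G77330
GENE - AT2G19590
GENE - AT1G62380
//
UNIQUE-ID - 2.6.1.5
COMMON-NAME - tyrosine transaminase
GENE - AT2G24850
GENE - AT2G20610
//
UNIQUE-ID - 4.1.1.50
COMMON-NAME - S-adenosylmethionine decarboxylase
GENE - AT5G18930
//
UNIQUE-ID - 2.8.1.9
COMMON-NAME - molybdenum-cofactor sulfurtransferase
GENE - AT1G16540
//
UNIQUE-ID - 2.4.1.12
COMMON-NAME - cellulose synthase
GENE - AT5G17420
GENE - AT4G32410
GENE - AT5G64740
GENE - AT5G05170
//
UNIQUE-ID - 1.13.11.51
COMMON-NAME - 9-cis-epoxycarotenoid dioxygenase
GENE - AT1G78390
//
UNIQUE-ID - 2.3.1.74
COMMON-NAME - naringenin-chalcone synthase
GENE - AT5G13930
//
UNIQUE-ID - 2.5.1.18
COMMON-NAME - glutathione transferase
GENE - AT2G47730
GENE - AT2G30870
GENE - AT2G30860
GENE - AT1G78380
//
UNIQUE-ID - 1.1.1.1
COMMON-NAME - alcohol dehydrogenase
GENE - AT1G77120
GENE - AT5G43940
GENE - AT5G19440
//
UNIQUE-ID - 1.13.11.12
COMMON-NAME - lipoxygenase
GENE - AT3G45140
GENE - AT1G17420
GENE - AT3G22400
GENE - AT1G67560
//
UNIQUE-ID - 5.4.4.2
COMMON-NAME - isochorismate synthase
GENE - AT1G74710
//
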