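# Curated Arabidopsis phytohormone crosstalk fixture.
# Transcribed from published pathway, regulation and expression knowledge
# for the eight major phytohormones; identifiers prefixed PLACEHOLDER-,
# ROUTE-LINKER- or MARKER- are synthetic fixture scaffolding that stands in
# for entities the curated source does not name.
UNIQUE-ID - 2-OXOGLUTARATE
COMMON-NAME - 2 oxoglutarate
//
UNIQUE-ID - 22A-HYDROXY-CAMPEST-4-EN-3-ONE
COMMON-NAME - 22a hydroxy campest 4 en 3 one
//
UNIQUE-ID - ACC
COMMON-NAME - acc
//
UNIQUE-ID - AMP
COMMON-NAME - amp
//
UNIQUE-ID - ATP
COMMON-NAME - atp
//
UNIQUE-ID - BRASSINOLIDE
COMMON-NAME - brassinolide
//
UNIQUE-ID - BRASSINOLIDE-23-O-GLUCOSIDE
COMMON-NAME - brassinolide 23 o glucoside
//
UNIQUE-ID - CASTASTERONE
COMMON-NAME - castasterone
//
UNIQUE-ID - CO2
COMMON-NAME - co2
//
UNIQUE-ID - DEHYDROASCORBATE
COMMON-NAME - dehydroascorbate
//
UNIQUE-ID - DIHYDROKAEMPFEROL
COMMON-NAME - dihydrokaempferol
//
UNIQUE-ID - ETHYLENE-CPD
COMMON-NAME - ethylene cpd
//
UNIQUE-ID - GIBBERELLIN-A20
COMMON-NAME - gibberellin a20
//
UNIQUE-ID - GIBBERELLIN-A20-METHYL-ESTER
COMMON-NAME - gibberellin a20 methyl ester
//
UNIQUE-ID - INDOLE-3-ACETALDEHYDE
COMMON-NAME - indole 3 acetaldehyde
//
UNIQUE-ID - INDOLE-3-ACETATE
COMMON-NAME - indole 3 acetate
//
UNIQUE-ID - INDOLE-3-ACETYL-BETA-D-GLUCOSE
COMMON-NAME - indole 3 acetyl beta d glucose
//
UNIQUE-ID - INDOLE-3-ACETYL-PHENYLALANINE
COMMON-NAME - indole 3 acetyl phenylalanine
//
UNIQUE-ID - JASMONATE
COMMON-NAME - jasmonate
//
UNIQUE-ID - JASMONOYL-ACC
COMMON-NAME - jasmonoyl acc
//
UNIQUE-ID - KAEMPFEROL
COMMON-NAME - kaempferol
//
UNIQUE-ID - KAEMPFEROL-3-O-GLUCOSIDE
COMMON-NAME - kaempferol 3 o glucoside
//
UNIQUE-ID - KETO-PHENYLPYRUVATE
COMMON-NAME - keto phenylpyruvate
//
UNIQUE-ID - L-ASCORBATE
COMMON-NAME - l ascorbate
//
UNIQUE-ID - L-GLUTAMATE
COMMON-NAME - l glutamate
//
UNIQUE-ID - L-PHENYLALANINE
COMMON-NAME - l phenylalanine
//
UNIQUE-ID - MARKER-XTALK-01
COMMON-NAME - marker xtalk 01
//
UNIQUE-ID - MARKER-XTALK-02
COMMON-NAME - marker xtalk 02
//
UNIQUE-ID - MARKER-XTALK-03
COMMON-NAME - marker xtalk 03
//
UNIQUE-ID - MARKER-XTALK-04
COMMON-NAME - marker xtalk 04
//
UNIQUE-ID - MARKER-XTALK-05
COMMON-NAME - marker xtalk 05
//
UNIQUE-ID - MARKER-XTALK-06
COMMON-NAME - marker xtalk 06
//
UNIQUE-ID - MARKER-XTALK-07
COMMON-NAME - marker xtalk 07
//
UNIQUE-ID - MARKER-XTALK-08
COMMON-NAME - marker xtalk 08
//
UNIQUE-ID - MARKER-XTALK-09
COMMON-NAME - marker xtalk 09
//
UNIQUE-ID - MARKER-XTALK-10
COMMON-NAME - marker xtalk 10
//
UNIQUE-ID - MARKER-XTALK-11
COMMON-NAME - marker xtalk 11
//
UNIQUE-ID - MARKER-XTALK-12
COMMON-NAME - marker xtalk 12
//
UNIQUE-ID - MARKER-XTALK-13
COMMON-NAME - marker xtalk 13
//
UNIQUE-ID - MARKER-XTALK-14
COMMON-NAME - marker xtalk 14
//
UNIQUE-ID - MARKER-XTALK-15
COMMON-NAME - marker xtalk 15
//
UNIQUE-ID - MARKER-XTALK-16
COMMON-NAME - marker xtalk 16
//
UNIQUE-ID - MARKER-XTALK-17
COMMON-NAME - marker xtalk 17
//
UNIQUE-ID - MARKER-XTALK-18
COMMON-NAME - marker xtalk 18
//
UNIQUE-ID - MARKER-XTALK-19
COMMON-NAME - marker xtalk 19
//
UNIQUE-ID - MARKER-XTALK-20
COMMON-NAME - marker xtalk 20
//
UNIQUE-ID - MARKER-XTALK-21
COMMON-NAME - marker xtalk 21
//
UNIQUE-ID - MARKER-XTALK-22
COMMON-NAME - marker xtalk 22
//
UNIQUE-ID - MARKER-XTALK-23
COMMON-NAME - marker xtalk 23
//
UNIQUE-ID - MARKER-XTALK-24
COMMON-NAME - marker xtalk 24
//
UNIQUE-ID - MARKER-XTALK-25
COMMON-NAME - marker xtalk 25
//
UNIQUE-ID - MARKER-XTALK-26
COMMON-NAME - marker xtalk 26
//
UNIQUE-ID - MARKER-XTALK-27
COMMON-NAME - marker xtalk 27
//
UNIQUE-ID - MARKER-XTALK-28
COMMON-NAME - marker xtalk 28
//
UNIQUE-ID - MARKER-XTALK-29
COMMON-NAME - marker xtalk 29
//
UNIQUE-ID - MARKER-XTALK-30
COMMON-NAME - marker xtalk 30
//
UNIQUE-ID - MARKER-XTALK-31
COMMON-NAME - marker xtalk 31
//
UNIQUE-ID - MARKER-XTALK-32
COMMON-NAME - marker xtalk 32
//
UNIQUE-ID - MARKER-XTALK-33
COMMON-NAME - marker xtalk 33
//
UNIQUE-ID - MARKER-XTALK-34
COMMON-NAME - marker xtalk 34
//
UNIQUE-ID - MARKER-XTALK-35
COMMON-NAME - marker xtalk 35
//
UNIQUE-ID - METHYL-INDOLE-3-ACETATE
COMMON-NAME - methyl indole 3 acetate
//
UNIQUE-ID - O2
COMMON-NAME - o2
//
UNIQUE-ID - PLACEHOLDER-BR2-PRODUCT
COMMON-NAME - placeholder br2 product
//
UNIQUE-ID - PLACEHOLDER-CAMPESTANOID
COMMON-NAME - placeholder campestanoid
//
UNIQUE-ID - PLACEHOLDER-CK7N-PRODUCT
COMMON-NAME - placeholder ck7n product
//
UNIQUE-ID - PLACEHOLDER-GA-PRECURSOR
COMMON-NAME - placeholder ga precursor
//
UNIQUE-ID - PLACEHOLDER-KAEMPFEROL-METHYL
COMMON-NAME - placeholder kaempferol methyl
//
UNIQUE-ID - PLACEHOLDER-L0405-PROD
COMMON-NAME - placeholder l0405 prod
//
UNIQUE-ID - PLACEHOLDER-L0405-SUB
COMMON-NAME - placeholder l0405 sub
//
UNIQUE-ID - PLACEHOLDER-L0708-PROD
COMMON-NAME - placeholder l0708 prod
//
UNIQUE-ID - PLACEHOLDER-L0708-SUB
COMMON-NAME - placeholder l0708 sub
//
UNIQUE-ID - PLACEHOLDER-L0910-PROD
COMMON-NAME - placeholder l0910 prod
//
UNIQUE-ID - PLACEHOLDER-L0910-SUB
COMMON-NAME - placeholder l0910 sub
//
UNIQUE-ID - PLACEHOLDER-L1112-PROD
COMMON-NAME - placeholder l1112 prod
//
UNIQUE-ID - PLACEHOLDER-L1112-SUB
COMMON-NAME - placeholder l1112 sub
//
UNIQUE-ID - PLACEHOLDER-MTA
COMMON-NAME - placeholder mta
//
UNIQUE-ID - PLACEHOLDER-QUERCETIN-METHYL
COMMON-NAME - placeholder quercetin methyl
//
UNIQUE-ID - PPI
COMMON-NAME - ppi
//
UNIQUE-ID - PROTON
COMMON-NAME - proton
//
UNIQUE-ID - QUERCETIN
COMMON-NAME - quercetin
//
UNIQUE-ID - QUERCETIN-3-O-GLUCOSIDE
COMMON-NAME - quercetin 3 o glucoside
//
UNIQUE-ID - ROUTE-LINKER-04-05
COMMON-NAME - route linker 04 05
//
UNIQUE-ID - ROUTE-LINKER-07-08
COMMON-NAME - route linker 07 08
//
UNIQUE-ID - ROUTE-LINKER-09-10
COMMON-NAME - route linker 09 10
//
UNIQUE-ID - ROUTE-LINKER-11-12
COMMON-NAME - route linker 11 12
//
UNIQUE-ID - S-ADENOSYL-L-HOMOCYSTEINE
COMMON-NAME - s adenosyl l homocysteine
//
UNIQUE-ID - S-ADENOSYL-L-METHIONINE
COMMON-NAME - s adenosyl l methionine
//
UNIQUE-ID - TRANS-DIHYDROQUERCETIN
COMMON-NAME - trans dihydroquercetin
//
UNIQUE-ID - TRANS-ZEATIN
COMMON-NAME - trans zeatin
//
UNIQUE-ID - TRANS-ZEATIN-O-GLUCOSIDE
COMMON-NAME - trans zeatin o glucoside
//
UNIQUE-ID - UDP
COMMON-NAME - udp
//
UNIQUE-ID - UDP-D-GLUCOSE
COMMON-NAME - udp d glucose
//
UNIQUE-ID - WATER
COMMON-NAME - water
//
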