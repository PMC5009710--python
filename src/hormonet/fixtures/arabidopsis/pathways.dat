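# Curated Arabidopsis phytohormone crosstalk fixture.
# Transcribed from published pathway, regulation and expression knowledge
# for the eight major phytohormones; identifiers prefixed PLACEHOLDER-,
# ROUTE-LINKER- or MARKER- are synthetic fixture scaffolding that stands in
# for entities the curated source does not name.
UNIQUE-ID - PWY-BRASSINOSTEROID-BIOSYNTHESIS-II
COMMON-NAME - brassinosteroid biosynthesis II
//
UNIQUE-ID - PWY-BRASSINOSTEROID-BIOSYNTHESIS-I
COMMON-NAME - brassinosteroid biosynthesis I
//
UNIQUE-ID - PWY-BRASSINOSTEROID-INACTIVATION
COMMON-NAME - brassinosteroid inactivation
//
UNIQUE-ID - PWY-CYTOKININ-7N-GLUCOSIDE-BIOSYNTHESIS
COMMON-NAME - cytokinin 7-N-glucoside biosynthesis
//
UNIQUE-ID - PWY-CYTOKININ-O-GLUCOSIDE-BIOSYNTHESIS
COMMON-NAME - cytokinin-O-glucoside biosynthesis
//
UNIQUE-ID - PWY-KAEMPFEROL-GLUCOSIDE-BIOSYNTHESIS
COMMON-NAME - kaempferol glucoside biosynthesis
//
UNIQUE-ID - PWY-QUERCETIN-GLUCOSIDE-BIOSYNTHESIS
COMMON-NAME - quercetin glucoside biosynthesis
//
UNIQUE-ID - PWY-FLAVONOL-BIOSYNTHESIS
COMMON-NAME - flavonol biosynthesis
//
UNIQUE-ID - PWY-QUERCETIN-SULFATE-BIOSYNTHESIS
COMMON-NAME - quercetin sulfate biosynthesis
//
UNIQUE-ID - PWY-GIBBERELLIN-INACTIVATION-II
COMMON-NAME - gibberellin inactivation II (methylation)
//
UNIQUE-ID - PWY-SAM-CYCLE-II
COMMON-NAME - S-adenosyl-L-methionine cycle II
//
UNIQUE-ID - PWY-GIBBERELLIN-BIOSYNTHESIS-III
COMMON-NAME - gibberellin biosynthesis III (early C-13 hydroxylation)
//
UNIQUE-ID - PWY-IAA-BIOSYNTHESIS-I
COMMON-NAME - IAA biosynthesis I
//
UNIQUE-ID - PWY-IAA-CONJUGATE-SUPERPATHWAY
COMMON-NAME - superpathway of IAA conjugate biosynthesis
//
UNIQUE-ID - PWY-IAA-DEGRADATION-V
COMMON-NAME - IAA degradation V
//
UNIQUE-ID - PWY-PHENYLALANINE-DEGRADATION-III
COMMON-NAME - phenylalanine degradation III
//
UNIQUE-ID - PWY-JA-CONJUGATE-BIOSYNTHESIS-I
COMMON-NAME - jasmonoyl-amino acid conjugates biosynthesis I
//
UNIQUE-ID - PWY-ETHYLENE-BIOSYNTHESIS-I
COMMON-NAME - ethylene biosynthesis I
//
UNIQUE-ID - PWY-ABA-CROSSTALK
COMMON-NAME - abscisic acid crosstalk membership
//
UNIQUE-ID - PWY-SA-CROSSTALK
COMMON-NAME - salicylic acid crosstalk membership
//
UNIQUE-ID - PWY-AUXIN-HOMEOSTASIS
COMMON-NAME - auxin homeostasis membership
//
UNIQUE-ID - PWY-CYTOKININ-HOMEOSTASIS
COMMON-NAME - cytokinin homeostasis membership
//
UNIQUE-ID - PWY-JA-CROSSTALK
COMMON-NAME - jasmonic acid crosstalk membership
//
UNIQUE-ID - PWY-GA-CROSSTALK
COMMON-NAME - gibberellin crosstalk membership
//
UNIQUE-ID - PWY-ETHYLENE-CROSSTALK
COMMON-NAME - ethylene crosstalk membership
//
UNIQUE-ID - PWY-ROUTE-SCAFFOLD
COMMON-NAME - route scaffold (placeholder linker reactions)
//
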