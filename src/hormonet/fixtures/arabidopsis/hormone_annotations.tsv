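hormone	pathway_id	role
brassinosteroid	PWY-BRASSINOSTEROID-BIOSYNTHESIS-II	biosynthesis
brassinosteroid	PWY-BRASSINOSTEROID-BIOSYNTHESIS-I	biosynthesis
brassinosteroid	PWY-BRASSINOSTEROID-INACTIVATION	inactivation
cytokinin	PWY-CYTOKININ-7N-GLUCOSIDE-BIOSYNTHESIS	conjugation
cytokinin	PWY-CYTOKININ-O-GLUCOSIDE-BIOSYNTHESIS	conjugation
cytokinin	PWY-CYTOKININ-HOMEOSTASIS	biosynthesis
gibberellin	PWY-GIBBERELLIN-INACTIVATION-II	inactivation
gibberellin	PWY-GIBBERELLIN-BIOSYNTHESIS-III	biosynthesis
gibberellin	PWY-GA-CROSSTALK	biosynthesis
auxin	PWY-IAA-BIOSYNTHESIS-I	biosynthesis
auxin	PWY-IAA-CONJUGATE-SUPERPATHWAY	conjugation
auxin	PWY-IAA-DEGRADATION-V	degradation
auxin	PWY-AUXIN-HOMEOSTASIS	biosynthesis
jasmonic acid	PWY-JA-CONJUGATE-BIOSYNTHESIS-I	conjugation
jasmonic acid	PWY-JA-CROSSTALK	biosynthesis
ethylene	PWY-ETHYLENE-BIOSYNTHESIS-I	biosynthesis
ethylene	PWY-ETHYLENE-CROSSTALK	biosynthesis
abscisic acid	PWY-ABA-CROSSTALK	biosynthesis
salicylic acid	PWY-SA-CROSSTALK	biosynthesis
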