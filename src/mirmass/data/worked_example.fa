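>hsa-miR-153 MIMAT0000439 Homo sapiens miR-153
UUGCAUAGUCACAAAAGUGAUC
>hsa-syn-miR-001 SYNT0000001 synthetic fixture record
ACAUUUGUCUAAUAUGUGCUUUC
>hsa-syn-miR-002 SYNT0000002 synthetic fixture record
GCCGCCUAGACGGCGGAAAAU
>hsa-syn-miR-003 SYNT0000003 synthetic fixture record
UGUGAACAUUUUACACAUUGUA
>hsa-syn-miR-004 SYNT0000004 synthetic fixture record
ACCGGGGUCCGCCGAUUGAACAGA
>hsa-syn-miR-005 SYNT0000005 synthetic fixture record
CCUGAAUGCCAAGAAACCCUUUAUCC
>hsa-syn-miR-006 SYNT0000006 synthetic fixture record
AUCACUGCUCCAGUCCGUC
>hsa-syn-miR-007 SYNT0000007 synthetic fixture record
ACGGGUUGCCUUGCGCAGCCAA
>hsa-syn-miR-008 SYNT0000008 synthetic fixture record
UAUGCCAUAAAAACACUAAACACAA
>hsa-syn-miR-009 SYNT0000009 synthetic fixture record
CAUAUAGGCGAUCUCG
>hsa-syn-miR-010 SYNT0000010 synthetic fixture record
UCAGGAGAUAACUGAUUCACU
>hsa-syn-miR-011 SYNT0000011 synthetic fixture record
AUGCCUCUCGGCCGUGC
>hsa-syn-miR-012 SYNT0000012 synthetic fixture record
UAGGAUCAUAAUGAAG
>hsa-syn-miR-013 SYNT0000013 synthetic fixture record
CGGUGCUUCGGUUCGUGGCCGUAUAC
>hsa-syn-miR-014 SYNT0000014 synthetic fixture record
AGGCAGUUUAUAUAUUUAAUCCAUC
>hsa-syn-miR-015 SYNT0000015 synthetic fixture record
GGACCACGCGUCCAUCCAUAAUCGAU
>hsa-syn-miR-016 SYNT0000016 synthetic fixture record
UGUUAACGUAGGAAAGCG
>hsa-syn-miR-017 SYNT0000017 synthetic fixture record
CUCCUCCUAUGCCCCU
>hsa-syn-miR-018 SYNT0000018 synthetic fixture record
UAUGCGGUAUAAGCUGGAGGCGCGAGG
>hsa-syn-miR-019 SYNT0000019 synthetic fixture record
GUGAAAGUGGCCCUAU
>hsa-syn-miR-020 SYNT0000020 synthetic fixture record
UUGUGUAGUGAACCCCAAUAGA
>hsa-syn-miR-021 SYNT0000021 synthetic fixture record
UUGGAACAUUUACCGAGAGGAAGC
>hsa-syn-miR-022 SYNT0000022 synthetic fixture record
GGGUGCGUACGCGGACUCGCGGGCUCAG
>hsa-syn-miR-901 SYNT0000901 synthetic fixture record (shares UUGCAUAGU 9-mer)
UUGCAUAGUAAGCCAUGGAAC
>hsa-syn-miR-902 SYNT0000902 synthetic fixture record (shares UUGCAUAGU 9-mer)
CACGGUUGCAUAGUGUUAGCU
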