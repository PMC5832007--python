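# Internal-chain residue formulas for RNA: nucleoside-5'-monophosphate minus water.
# Summing these over a sequence and adding one H2O yields the
# 5'-phosphate / 3'-hydroxyl oligonucleotide.
# base	formula
A	C10H12N5O6P
C	C9H12N3O7P
G	C10H12N5O7P
U	C9H11N2O8P
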