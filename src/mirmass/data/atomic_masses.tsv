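# Atomic masses used for RNA oligonucleotide mass computation.
# monoisotopic: mass of the principal (lightest stable) isotope, Da
# average: IUPAC standard atomic weight, Da
# Users may substitute their own table via AtomicMassTable.from_tsv().
# element	monoisotopic	average
H	1.00782503207	1.00794
C	12.0	12.0107
N	14.0030740048	14.0067
O	15.9949146196	15.9994
P	30.97376163	30.973762
S	31.97207100	32.065
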