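# Curated default table of common post-transcriptional RNA modifications.
# Columns (tab-separated): short code, full name, parent base, elemental delta formula.
# The delta formula is the signed elemental-composition difference relative to the
# unmodified nucleotide, e.g. "+CH2" for any methylation; "+0" means mass-silent
# (pseudouridine is an isomerization of uridine and shifts no mass).
# Parent base "any" means the modification is not tied to a single base.
# code	name	parent	delta
m6A	N6-methyladenosine	A	+CH2
m1A	1-methyladenosine	A	+CH2
Am	2'-O-methyladenosine	A	+CH2
m5C	5-methylcytidine	C	+CH2
Cm	2'-O-methylcytidine	C	+CH2
ac4C	N4-acetylcytidine	C	+C2H2O
m7G	7-methylguanosine	G	+CH2
m1G	1-methylguanosine	G	+CH2
Gm	2'-O-methylguanosine	G	+CH2
m5U	5-methyluridine	U	+CH2
Um	2'-O-methyluridine	U	+CH2
Y	pseudouridine	U	+0
D	dihydrouridine	U	+H2
s2U	2-thiouridine	U	+S-O
s4U	4-thiouridine	U	+S-O
I	inosine	A	-H-N+O
i6A	N6-isopentenyladenosine	A	+C5H8
t6A	N6-threonylcarbamoyladenosine	A	+C5H7NO4
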