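# Cell-line names whose surface form mimics a wNm substitution mention.
# One entry per line; matching is case-insensitive after whitespace
# normalization.  Extend with a full catalogue (e.g. Cellosaurus) for
# production corpora.
T47D
U266
U937
K562
A431
A549
H460
H1299
T24
J82
U87
U2OS
HL60
HT29
SW480
SW620
HCT116
DU145
PC3
BT474
CAL51
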