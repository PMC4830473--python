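# Gene symbols whose surface form mimics a wNm substitution mention.
# Replace or extend with the full HUGO list for production corpora.
S100B
S100A4
H19
P2RX7
C5AR1
F2RL1
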