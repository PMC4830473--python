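# Microarray / assay platform names that look like substitution mentions.
U133A
U133B
U95A
U95B
U95C
U219
X3P
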