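# Minimal mitochondrial gene model for annotation demos and tests.
# The ND4 span is trimmed to 10760-12136 (1377 nt) so the coding length is
# an exact codon multiple (the genomic gene ends in an incomplete stop codon
# completed by polyadenylation, which this model does not represent).
gene	start	end	strand	phase	coding	wrap
ND4	10760	12136	+	0	coding	0
TRNH	12138	12206	+	0	noncoding	0
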