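# Human mitochondrial codon usage, frequency per thousand (kazusa.or.jp
# codon-usage snapshot values for the two threonine codons of interest;
# extend with further rows as needed).
codon	frequency_per_thousand
ACA	32.7
ACG	2.6
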