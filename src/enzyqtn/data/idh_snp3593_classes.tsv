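# Published genotype-class means of standardized maize IDH activity at the
# focal idh SNP (SNP3593, Phe/Tyr209), pooled over 26 inbreds and 61
# testcross hybrids after per-background standardization.
genotype	n	mean_activity
AA	16	0.6182
AT	29	0.0302
TT	41	-0.2626
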