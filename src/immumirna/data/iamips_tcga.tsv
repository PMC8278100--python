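# IAMIPS: three-miRNA immune-associated prognostic signature.
# Coefficients are the published penalized-Cox training constants on
# z-scored miRNA expression; the cutoff is the training-cohort optimum.
cutoff=0.05
mirna_id	coefficient
hsa-miR-216a-5p	0.015
hsa-miR-194-3p	-0.035
hsa-miR-3677-3p	-0.124
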