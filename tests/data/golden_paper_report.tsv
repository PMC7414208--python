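stratum	label	n	OR	five-region CI	AUC	bootstrap CI	conclusion
all	all	278	0.85	[0.50, 1.49]	0.49	[0.44, 0.54]	statistically equivalent within [0.5, 2]
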