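mirna_set	n_mirnas	gene_list	ffls	p_printed
SZmiRNAs	29	160	32
SZmiRNAs	29	75	12
SZmiRNAs	29	124	27
SZmiRNAs	29	270	38
Brain miRNAs	105	160	55	0.020
Brain miRNAs	105	75	26	0.204
Brain miRNAs	105	124	49	0.035
Brain miRNAs	105	270	87	0.120
Non-brain miRNAs	94	160	24	1.80e-5
Non-brain miRNAs	94	75	11	9.86e-3
Non-brain miRNAs	94	124	20	4.79e-5
Non-brain miRNAs	94	270	27	2.97e-7
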