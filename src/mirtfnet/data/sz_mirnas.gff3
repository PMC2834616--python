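##gff-version 3
# Schizophrenia-associated miRNA precursors: genomic location, host gene
# relation and taxonomic conservation class (V vertebrate, M mammal-specific,
# P primate-specific, A conserved to Drosophila). Coordinates 1-based inclusive.
3	mirtfnet	miRNA_primary_transcript	52277334	52277417	.	-	.	ID=hsa-let-7g;family=hsa-let-7g;matures=hsa-let-7g;host_gene=WDR82;host_relation=intronic;conservation=V
7	mirtfnet	miRNA_primary_transcript	99529552	99529633	.	-	.	ID=hsa-miR-106b;family=hsa-miR-106b;matures=hsa-miR-106b;host_gene=MCM7;host_relation=intronic;conservation=V
1	mirtfnet	miRNA_primary_transcript	197094625	197094734	.	-	.	ID=hsa-miR-181b-1;family=hsa-miR-181b;matures=hsa-miR-181b;host_gene=INTERGENIC;host_relation=intergenic;conservation=V
9	mirtfnet	miRNA_primary_transcript	126495810	126495898	.	+	.	ID=hsa-miR-181b-2;family=hsa-miR-181b;matures=hsa-miR-181b;host_gene=NR6A1;host_relation=antisense;conservation=V
17	mirtfnet	miRNA_primary_transcript	6861658	6861744	.	-	.	ID=hsa-miR-195;family=hsa-miR-195;matures=hsa-miR-195;host_gene=INTERGENIC;host_relation=intergenic;conservation=M
3	mirtfnet	miRNA_primary_transcript	121597205	121597266	.	-	.	ID=hsa-miR-198;family=hsa-miR-198;matures=hsa-miR-198;host_gene=FSTL1;host_relation=utr3;conservation=P
6	mirtfnet	miRNA_primary_transcript	52117106	52117191	.	+	.	ID=hsa-miR-206;family=hsa-miR-206;matures=hsa-miR-206;host_gene=INTERGENIC;host_relation=intergenic;conservation=M
X	mirtfnet	miRNA_primary_transcript	133131505	133131573	.	-	.	ID=hsa-miR-20b;family=hsa-miR-20b;matures=hsa-miR-20b;host_gene=INTERGENIC;host_relation=intergenic;conservation=V
17	mirtfnet	miRNA_primary_transcript	1900315	1900424	.	-	.	ID=hsa-miR-212;family=hsa-miR-212;matures=hsa-miR-212;host_gene=INTERGENIC;host_relation=intergenic;conservation=V
9	mirtfnet	miRNA_primary_transcript	96888124	96888191	.	+	.	ID=hsa-miR-24-1;family=hsa-miR-24;matures=hsa-miR-24;host_gene=C9orf3;host_relation=intronic;conservation=V
19	mirtfnet	miRNA_primary_transcript	13808101	13808173	.	-	.	ID=hsa-miR-24-2;family=hsa-miR-24;matures=hsa-miR-24;host_gene=INTERGENIC;host_relation=intergenic;conservation=V
2	mirtfnet	miRNA_primary_transcript	218975613	218975689	.	+	.	ID=hsa-miR-26b;family=hsa-miR-26b;matures=hsa-miR-26b;host_gene=CTDSP1;host_relation=intronic;conservation=V
7	mirtfnet	miRNA_primary_transcript	130212046	130212109	.	-	.	ID=hsa-miR-29a;family=hsa-miR-29a;matures=hsa-miR-29a;host_gene=AP4M1;host_relation=antisense;conservation=V
7	mirtfnet	miRNA_primary_transcript	130212758	130212838	.	-	.	ID=hsa-miR-29b-1;family=hsa-miR-29b;matures=hsa-miR-29b;host_gene=AP4M1;host_relation=antisense;conservation=V
1	mirtfnet	miRNA_primary_transcript	206042411	206042491	.	-	.	ID=hsa-miR-29b-2;family=hsa-miR-29b;matures=hsa-miR-29b;host_gene=INTERGENIC;host_relation=intergenic;conservation=V
1	mirtfnet	miRNA_primary_transcript	206041820	206041907	.	-	.	ID=hsa-miR-29c;family=hsa-miR-29c;matures=hsa-miR-29c;host_gene=INTERGENIC;host_relation=intergenic;conservation=V
6	mirtfnet	miRNA_primary_transcript	72169975	72170045	.	-	.	ID=hsa-miR-30a;family=hsa-miR-30a;matures=hsa-miR-30a;host_gene=C6orf155;host_relation=intronic;conservation=V
8	mirtfnet	miRNA_primary_transcript	135881945	135882032	.	-	.	ID=hsa-miR-30b;family=hsa-miR-30b;matures=hsa-miR-30b;host_gene=INTERGENIC;host_relation=intergenic;conservation=V
8	mirtfnet	miRNA_primary_transcript	135886301	135886370	.	-	.	ID=hsa-miR-30d;family=hsa-miR-30d;matures=hsa-miR-30d;host_gene=INTERGENIC;host_relation=intergenic;conservation=V
1	mirtfnet	miRNA_primary_transcript	40992614	40992705	.	+	.	ID=hsa-miR-30e;family=hsa-miR-30e;matures=hsa-miR-30e;host_gene=NFYC;host_relation=intronic;conservation=V
9	mirtfnet	miRNA_primary_transcript	85774483	85774592	.	-	.	ID=hsa-miR-7-1;family=hsa-miR-7;matures=hsa-miR-7;host_gene=HNRNPK;host_relation=intronic;conservation=A
15	mirtfnet	miRNA_primary_transcript	86956060	86956169	.	+	.	ID=hsa-miR-7-2;family=hsa-miR-7;matures=hsa-miR-7;host_gene=INTERGENIC;host_relation=intergenic;conservation=A
19	mirtfnet	miRNA_primary_transcript	4721682	4721791	.	+	.	ID=hsa-miR-7-3;family=hsa-miR-7;matures=hsa-miR-7;host_gene=C19orf30;host_relation=intronic;conservation=A
1	mirtfnet	miRNA_primary_transcript	154656757	154656845	.	-	.	ID=hsa-miR-9-1;family=hsa-miR-9;matures=hsa-miR-9;host_gene=C1orf61;host_relation=intronic;conservation=A
5	mirtfnet	miRNA_primary_transcript	87998427	87998513	.	-	.	ID=hsa-miR-9-2;family=hsa-miR-9;matures=hsa-miR-9;host_gene=INTERGENIC;host_relation=intergenic;conservation=A
15	mirtfnet	miRNA_primary_transcript	87712252	87712341	.	+	.	ID=hsa-miR-9-3;family=hsa-miR-9;matures=hsa-miR-9;host_gene=INTERGENIC;host_relation=intergenic;conservation=A
13	mirtfnet	miRNA_primary_transcript	90801569	90801646	.	+	.	ID=hsa-miR-92a-1;family=hsa-miR-92a;matures=hsa-miR-92a;host_gene=INTERGENIC;host_relation=intergenic;conservation=A
X	mirtfnet	miRNA_primary_transcript	133131234	133131308	.	-	.	ID=hsa-miR-92a-2;family=hsa-miR-92a;matures=hsa-miR-92a;host_gene=INTERGENIC;host_relation=intergenic;conservation=A
1	mirtfnet	miRNA_primary_transcript	153431592	153431687	.	+	.	ID=hsa-miR-92b;family=hsa-miR-92b;matures=hsa-miR-92b;host_gene=INTERGENIC;host_relation=intergenic;conservation=A
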