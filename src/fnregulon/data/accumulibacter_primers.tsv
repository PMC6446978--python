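gene_id	gene_length_bp	forward_start	forward_end	forward_seq	reverse_start	reverse_end	reverse_seq	declared_amplicon_bp
nirS-1	1739	147	164	GTCGGCGATCGCGCAAT	291	311	AGCGTTTTGTCCGTAGTCAGA	164
narG	3819	336	353	CCGATGGTTCGCGGTCA	403	424	CGGACTCGACGATCGATGTCC	91
norZ	2282	1846	1864	CTTTGGGCTGGGTGGGT	2204	2221	CGCGATCGGCGCTCAAAC	375
nosZ	2297	591	616	AAGAAATTCGAGCCACTAGAGGAAT	935	954	AACATCCAGCGGCAATACG	363
ccoN	1428	241	260	CCTGCCATACGCGACTTTT	344	365	TCGGCATACTCTTTGGACTGG	124
ctaD	1611	816	834	TCGCATGTCATCCCTGCC	932	951	GGTCAGCGGAATACCGGTC	135
rpoN	1440	153	170	GAGTACGCGCGGACGGA	594	611	TGTGCGCTGCGAGCCCC	487
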