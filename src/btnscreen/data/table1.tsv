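individual	locus	tissue	allele	colony_count	total_major	total_all	printed_freq	method
J54	EF1a	hemolymph	1	1	12	16	0.08	cloning
J54	EF1a	hemolymph	D	7	12	16	0.58	cloning
J54	EF1a	hemolymph	G	2	12	16	0.17	cloning
J54	EF1a	hemolymph	G1	1	12	16	0.08	cloning
J54	EF1a	hemolymph	H	1	12	16	0.08	cloning
J54	EF1a	foot	1	10	14	16	0.71	cloning
J54	EF1a	foot	D	1	14	16	0.07	cloning
J54	EF1a	foot	3	3	14	16	0.21	cloning
J54	CR	hemolymph	1	16	16	16	1.0	cloning
J54	CR	foot	3	.	.	.	.	direct
J54	COI	hemolymph	1	.	.	.	.	direct
J54	COI	hemolymph	3	.	.	.	.	direct
J54	COI	foot	3	.	.	.	.	direct
J111	EF1a	hemolymph	2	2	23	25	0.09	cloning
J111	EF1a	hemolymph	4	2	23	25	0.09	cloning
J111	EF1a	hemolymph	5	2	23	25	0.09	cloning
J111	EF1a	hemolymph	G	11	23	25	0.48	cloning
J111	EF1a	hemolymph	G1	1	23	25	0.04	cloning
J111	EF1a	hemolymph	H	5	23	25	0.22	cloning
J111	EF1a	foot	2	4	16	16	0.25	cloning
J111	EF1a	foot	4	10	16	16	0.63	cloning
J111	EF1a	foot	H	2	16	16	0.12	cloning
J111	CR	hemolymph	4	6	11	16	0.55	cloning
J111	CR	hemolymph	2	5	11	16	0.45	cloning
J111	CR	foot	4	.	.	.	.	direct
J111	COI	hemolymph	2	.	.	.	.	direct
J111	COI	hemolymph	4	.	.	.	.	direct
J111	COI	foot	4	.	.	.	.	direct
J161	EF1a	hemolymph	D	6	18	24	0.33	cloning
J161	EF1a	hemolymph	G	7	18	24	0.39	cloning
J161	EF1a	hemolymph	H	5	18	24	0.28	cloning
J161	EF1a	foot	6	5	12	16	0.31	cloning
J161	EF1a	foot	7	4	12	16	0.25	cloning
J161	EF1a	foot	G	2	12	16	0.12	cloning
J161	EF1a	foot	H	1	12	16	0.06	cloning
J161	CR	hemolymph	1	10	15	16	0.67	cloning
J161	CR	hemolymph	1'	5	15	16	0.33	cloning
J161	CR	foot	5	.	.	.	.	direct
J161	COI	hemolymph	1	.	.	.	.	direct
J161	COI	hemolymph	5	.	.	.	.	direct
J161	COI	foot	5	.	.	.	.	direct
J181	EF1a	hemolymph	G	24	37	43	0.65	cloning
J181	EF1a	hemolymph	H	13	37	43	0.35	cloning
J181	EF1a	foot	8	12	16	16	0.75	cloning
J181	EF1a	foot	9	4	16	16	0.25	cloning
J181	CR	hemolymph	6	3	12	16	0.19	cloning
J181	CR	hemolymph	2	9	12	16	0.56	cloning
J181	CR	foot	6	.	.	.	.	direct
J181	COI	hemolymph	2	.	.	.	.	direct
J181	COI	hemolymph	6	.	.	.	.	direct
J181	COI	foot	6	.	.	.	.	direct
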