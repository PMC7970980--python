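role	locus	note	namespace
btn_reference_panel	EF1a	BTN1/BTN2-specific alleles and host alleles from prior BTN surveys	NCBI GenBank (study supplementary accession list)
btn_reference_panel	COI	BTN COI alleles incl. the major BTN2 B-group alleles	NCBI GenBank (study supplementary accession list)
btn_reference_panel	CR	recombinant BTN2 control regions CR-C/CR-D and host F/M references	NCBI GenBank (study supplementary accession list)
btn_reference_panel	16S	F- and M-mtDNA 16S references for mitochondrial sexing	NCBI GenBank (study supplementary accession list)
related_genome	mitogenome	Baltic mussel mosaic mitogenome 62mc10	KM192133
related_sequence	COI	Northeast Pacific sequence identical to a cancer allele	KF931805
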