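#Clinically validated STR loci: motif, a typical normal repeat count, and the reportable pathogenic threshold.
gene	motif	normal_repeats	pathogenic_threshold
AR	CAG	22	35
ATN1	CAG	16	36
HTT	CAG	17	36
ATXN7	CAG	8	27
ATXN1	CAG	29	36
ATXN3	CTG	24	27
C9ORF72	GGGGCC	2	25
FXN	GAA	8	60
DMPK	CTG	21	36
FMR1	CGG	30	45
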