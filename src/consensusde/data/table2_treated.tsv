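gene	regulation	log2fc	occurrences	opposite_n	virus_status	virus_log2fc	virus_occurrences	virus_opposite_n	inflammation_status	inflammation_log2fc	inflammation_occurrences	inflammation_opposite_n	autoimmune_status	autoimmune_log2fc	autoimmune_occurrences	autoimmune_opposite_n
RSAD2	up	2.52	14	1	ns	NA	NA	0	up	1.35	1	0	up	2.36	4	0
MX1	up	1.92	11	1	ns	NA	NA	0	ns	NA	NA	0	up	1.66	4	0
IFI44L	up	2.99	10	1	ns	NA	NA	0	ns	NA	NA	0	up	2.25	7	0
IFI27	up	4.05	10	1	up	2.25	2	0	ns	NA	NA	0	up	4.04	5	0
BIRC4BP	up	1.54	10	1	ns	NA	NA	0	ns	NA	NA	0	up	1.54	3	0
HERC5	up	1.96	10	1	ns	NA	NA	0	ns	NA	NA	0	up	1.73	6	0
ISG15	up	2.15	10	1	up	1.33	1	0	ns	NA	NA	0	up	1.98	6	0
SIGLEC1	up	2.83	10	1	up	1.95	1	0	ns	NA	NA	0	up	2.88	2	0
SPATS2L	up	1.8	9	1	ns	NA	NA	0	ns	NA	NA	0	up	1.76	4	0
PLSCR1	up	1.32	9	1	ns	NA	NA	0	up	1.10	2	0	up	1.58	1	0
USP18	up	2.58	9	1	ns	NA	NA	0	ns	NA	NA	0	up	2.41	4	0
EIF2AK2	up	1.35	9	1	ns	NA	NA	0	ns	NA	NA	0	up	0.15	4	2
IFI44	up	1.69	9	1	ns	NA	NA	0	ns	NA	NA	0	up	1.88	5	0
IFIH1	up	1.44	9	1	ns	NA	NA	0	ns	NA	NA	0	up	1.1	4	0
OAS2	up	1.56	9	1	ns	NA	NA	0	ns	NA	NA	0	up	1.63	5	0
EPSTI1	up	1.69	9	1	up	1.26	1	0	up	1.12	2	0	up	2	2	0
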