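gene	regulation	log2fc	occurrences	opposite_n	virus_status	virus_log2fc	virus_occurrences	virus_opposite_n	inflammation_status	inflammation_log2fc	inflammation_occurrences	inflammation_opposite_n	autoimmune_status	autoimmune_log2fc	autoimmune_occurrences	autoimmune_opposite_n
ANKRD10	up	2.21	4	0	ns	NA	NA	0	ns	NA	NA	0	ns	NA	NA	0
ADD2	up	2.12	3	0	ns	NA	NA	0	ns	NA	NA	0	ns	NA	NA	0
SLC8A1	up	3.11	3	1	ns	NA	NA	0	ns	NA	NA	0	down	-1.24	1	0
MALAT1	down	-1.92	3	1	ns	NA	NA	0	ns	NA	NA	0	down	-1.66	2	0
C1ORF228	up	1.28	3	0	down	-1.27	1	0	ns	NA	NA	0	up	1.66	1	0
SSTR2	down	-2.32	3	0	ns	NA	NA	0	ns	NA	NA	0	ns	NA	NA	0
F5	down	-1.4	3	1	ns	NA	NA	0	ns	NA	NA	0	ns	NA	NA	0
CNTNAP2	down	-3.21	3	1	down	-1.25	1	0	down	-1.08	1	0	up	2.03	1	0
TAF9B	up	1.91	3	0	ns	NA	NA	0	ns	NA	NA	0	ns	NA	NA	0
LPP	up	1.48	3	1	down	-1.64	1	0	ns	NA	NA	0	ns	NA	NA	0
PAWR	down	-2.09	3	0	ns	NA	NA	0	ns	NA	NA	0	ns	NA	NA	0
RIF1	down	-1.64	3	0	ns	NA	NA	0	ns	NA	NA	0	up	1.38	1	0
PDE4DIP	up	1.27	3	0	ns	NA	NA	0	up	1.11	1	0	ns	NA	NA	0
SMAD4	up	1.56	3	0	ns	NA	NA	0	ns	NA	NA	0	up	1.2	1	0
DKK3	up	1.86	3	0	ns	NA	NA	0	ns	NA	NA	0	ns	NA	NA	0
MDM4	up	1.58	3	1	ns	NA	NA	0	ns	NA	NA	0	ns	NA	NA	0
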