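patient_id	ts_p	ts_r	germ_p	germ_r	coefficient
1	10	4	187	51	-175.5
2	0	16	5	66	-62.0
3	4	19	191	30	-6.0
4	0	19	10	160	40.5
5	4	19	265	223	-64.0
6	0	0	219	110	-23.5
7	0	21	3	84	-1.0
8	0	6	36	115	40.5
9	9	10	277	231	12.5
10	0	0	55	59	-110.0
11	2	12	3	62	-32.5
12	2	2	51	49	-138.5
13	12	14	219	113	15.0
14	0	1	1	2	-3.0
15	3	4	350	172	-135.5
16	2	6	141	55	-74.5
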