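progeny_id	mother_genotype	father_genotype	progeny_size	n_females	males_tested	males_infected	females_tested	females_infected
I-F1-1	XY	XY	17	17	0	0	3	3
I-F2-1	XX	XY	24	24	0	0	24	24
I-F2-2	YY	XY	32	0	32	0	0	0
I-F2-3	XX	XY	52	52	0	0	2	2
I-F3-1	XY	XY	68	68	0	0	12	12
I-F3-2	XX	XY	33	33	0	0	10	8
I-F3-3	XX	XY	59	59	0	0	12	12
I-F3-4	XX	XY	40	40	0	0	10	9
I-F4-1	XX	XY	50	39	11	0	15	12
I-F4-2	XX	XY	41	24	17	0	13	0
I-F4-3	XX	XY	32	10	22	0	10	2
I-F4-4	XX	XY	16	16	0	0	10	9
I-F4-5	XX	XY	51	51	0	0	15	15
I-F4-6	XY	XY	42	19	23	0	13	7
II-F1-1	XX	XY	13	13	0	0	2	2
II-F2-1	XY	YY	60	60	0	0	60	60
II-F2-2	XY	XY	20	20	0	0	1	1
II-F3-1	YY	XY	28	0	28	0	0	0
II-F3-2	YY	XY	42	0	42	0	0	0
II-F3-3	YY	XY	57	0	57	0	0	0
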