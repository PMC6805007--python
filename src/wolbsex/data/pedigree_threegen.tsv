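individual_id	family_id	mother_id	father_id	sex	y_marker	wolbachia	qpcr_ratio
I-F0-M	F0			female	positive	infected	
I-F0-F	F0			male	untested	untested	
I-F1-01	I-F1-1	I-F0-M	I-F0-F	female	negative	infected	0.02
I-F1-02	I-F1-1	I-F0-M	I-F0-F	female	positive	infected	0.97
I-F1-03	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-04	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-05	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-06	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-07	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-08	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-09	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-10	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-11	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-12	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-13	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-14	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-15	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-16	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F1-17	I-F1-1	I-F0-M	I-F0-F	female	untested	untested	
I-F2-1-F	SIRE			male	untested	uninfected	0.49
I-F2-2-F	SIRE			male	untested	uninfected	0.53
I-F2-1-01	I-F2-1	I-F1-01	I-F2-1-F	female	positive	infected	
I-F2-1-02	I-F2-1	I-F1-01	I-F2-1-F	female	positive	infected	
I-F2-1-03	I-F2-1	I-F1-01	I-F2-1-F	female	positive	infected	
I-F2-1-04	I-F2-1	I-F1-01	I-F2-1-F	female	positive	infected	
I-F2-1-05	I-F2-1	I-F1-01	I-F2-1-F	female	positive	infected	
I-F2-1-06	I-F2-1	I-F1-01	I-F2-1-F	female	positive	infected	
I-F2-1-07	I-F2-1	I-F1-01	I-F2-1-F	female	positive	infected	
I-F2-1-08	I-F2-1	I-F1-01	I-F2-1-F	female	positive	infected	
I-F2-1-09	I-F2-1	I-F1-01	I-F2-1-F	female	positive	infected	
I-F2-1-10	I-F2-1	I-F1-01	I-F2-1-F	female	positive	infected	
I-F2-1-11	I-F2-1	I-F1-01	I-F2-1-F	female	positive	infected	
I-F2-1-12	I-F2-1	I-F1-01	I-F2-1-F	female	negative	infected	
I-F2-1-13	I-F2-1	I-F1-01	I-F2-1-F	female	negative	infected	
I-F2-1-14	I-F2-1	I-F1-01	I-F2-1-F	female	negative	infected	
I-F2-1-15	I-F2-1	I-F1-01	I-F2-1-F	female	negative	infected	
I-F2-1-16	I-F2-1	I-F1-01	I-F2-1-F	female	negative	infected	
I-F2-1-17	I-F2-1	I-F1-01	I-F2-1-F	female	negative	infected	
I-F2-1-18	I-F2-1	I-F1-01	I-F2-1-F	female	negative	infected	
I-F2-1-19	I-F2-1	I-F1-01	I-F2-1-F	female	negative	infected	
I-F2-1-20	I-F2-1	I-F1-01	I-F2-1-F	female	negative	infected	
I-F2-1-21	I-F2-1	I-F1-01	I-F2-1-F	female	negative	infected	
I-F2-1-22	I-F2-1	I-F1-01	I-F2-1-F	female	negative	infected	
I-F2-1-23	I-F2-1	I-F1-01	I-F2-1-F	female	negative	infected	
I-F2-1-24	I-F2-1	I-F1-01	I-F2-1-F	female	negative	infected	
I-F2-2-01	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.44
I-F2-2-02	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.46
I-F2-2-03	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.47
I-F2-2-04	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.48
I-F2-2-05	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.49
I-F2-2-06	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.50
I-F2-2-07	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.50
I-F2-2-08	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.51
I-F2-2-09	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.52
I-F2-2-10	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.53
I-F2-2-11	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.54
I-F2-2-12	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.55
I-F2-2-13	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.56
I-F2-2-14	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.57
I-F2-2-15	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.58
I-F2-2-16	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.88
I-F2-2-17	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.90
I-F2-2-18	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.92
I-F2-2-19	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.93
I-F2-2-20	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.95
I-F2-2-21	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.96
I-F2-2-22	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.97
I-F2-2-23	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.98
I-F2-2-24	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	0.99
I-F2-2-25	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	1.00
I-F2-2-26	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	1.01
I-F2-2-27	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	1.02
I-F2-2-28	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	1.04
I-F2-2-29	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	1.05
I-F2-2-30	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	1.07
I-F2-2-31	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	1.10
I-F2-2-32	I-F2-2	I-F1-02	I-F2-2-F	male	positive	uninfected	1.12
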