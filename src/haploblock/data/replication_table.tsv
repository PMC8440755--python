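chrom	start_bp	phenotype	block_disc	block_rep	complete_disc	complete_rep	single_disc	single_rep
1	215146807	FCMpost_L	7.30E-17	1.25E-04	1.45E-13	6.26E-09	6.79E-12	9.23E-08
1	215146807	FCMpost_R	1.37E-14	2.57E-04	1.36E-12	1.79E-07	1.65E-09	1.34E-05
1	215146807	FIP_L	ns	nt	7.87E-04	1.88E-02	ns	nt
1	215146807	FIP_R	1.35E-03	ns	2.44E-05	1.04E-02	5.64E-04	8.22E-03
1	215146807	FPO_R	3.77E-03	ns	4.12E-06	ns	5.33E-05	3.26E-05
1	215146807	SC_R	ns	nt	2.86E-05	6.46E-04	3.44E-03	8.01E-04
1	215146807	SFint_L	ns	nt	4.98E-02	8.66E-03	ns	nt
1	215146807	SFsup_R	ns	nt	1.08E-02	1.69E-04	ns	nt
1	215146807	SPaint_L	1.89E-04	1.24E-02	5.72E-05	2.31E-03	ns	nt
1	215146807	SpC_L	1.09E-04	ns	8.12E-07	4.51E-02	1.95E-03	ns
1	215146807	SsP_L	3.51E-03	ns	2.97E-06	2.45E-02	4.03E-03	1.34E-02
7	134416326	INSULA_L	1.22E-02	ns	ns	nt	ns	nt
7	134416326	INSULA_R	2.61E-02	ns	ns	nt	4.21E-02	ns
9	113659382	FCMpost_R	9.55E-03	2.91E-03	4.14E-02	2.33E-04	3.43E-02	2.58E-04
9	113659382	SPaint_L	ns	nt	3.33E-02	2.62E-03	2.84E-02	3.38E-03
12	106476140	FCLp_R	ns	nt	5.10E-04	6.18E-03	9.41E-05	4.67E-03
12	106476140	SFint_R	4.25E-04	3.10E-03	9.22E-05	4.43E-04	8.20E-06	1.92E-04
12	106476140	SPeCinter_L	ns	nt	ns	nt	1.29E-02	7.44E-03
12	106476140	STsterascant_R	ns	nt	1.33E-02	7.65E-04	2.40E-03	3.25E-04
12	106476140	STsterascpost_L	ns	nt	ns	nt	1.81E-02	ns
16	87226206	SFinf_L	2.01E-03	1.25E-03	1.28E-04	2.73E-04	2.55E-05	2.71E-05
16	87226206	SFinfant_L	ns	nt	ns	nt	3.14E-02	7.07E-05
16	87226206	SFinfant_R	2.04E-06	ns	1.00E-06	1.01E-02	7.03E-09	1.05E-02
16	87226206	SFinter_R	3.36E-02	2.16E-03	1.36E-02	8.46E-05	1.37E-03	3.11E-05
16	87226206	SFmarginal_L	ns	nt	1.05E-02	8.78E-04	3.13E-02	2.50E-04
16	87245155	SFinf_L	8.33E-04	5.82E-04	5.96E-03	nt	1.65E-04	4.01E-03
16	87254180	SFinf_L	1.31E-03	2.94E-06	3.76E-02	1.13E-05	ns	nt
16	87254180	SFinfant_L	ns	nt	5.42E-03	8.45E-04	5.39E-03	1.09E-03
16	87254180	SFinfant_R	1.80E-02	1.21E-03	5.81E-03	5.83E-05	5.20E-03	4.71E-05
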