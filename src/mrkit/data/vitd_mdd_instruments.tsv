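rsid	chromosome	nearby_gene	effect_allele	eaf	beta_exposure	se_exposure	pvalue_exposure	beta_outcome	se_outcome	pvalue_outcome	n_cases	n_controls
rs3755967	4	GC	T	0.28	-0.089	0.002	4.74e-343	0.009	0.009	0.31	59851	113154
rs12785878	11	DHCR7	G	0.25	-0.036	0.002	3.80e-62	-0.006	0.010	0.52	45591	97674
rs10741657	11	CYP2R1	G	0.60	-0.031	0.002	2.05e-46	0.009	0.008	0.25	59851	113154
rs17216707	20	CYP24A1	C	0.21	-0.026	0.003	8.14e-23	-0.002	0.010	0.85	59851	113154
rs10745742	12	AMDHD1	C	0.60	-0.017	0.002	1.88e-14	-0.008	0.008	0.32	59851	113154
rs8018720	14	SEC23A	C	0.82	-0.017	0.003	4.72e-9	-0.003	0.011	0.76	58854	106796
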