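variant_id	gene	chromosome	effect_allele	other_allele	beta_exposure	se_exposure	beta_outcome	se_outcome
rs10741657	CYP2R1	11	A	G	0.0312	0.0022	0.0162	0.0135
rs10745742	AMDHD1	12	T	C	0.0167	0.0022	-0.0049	0.0138
rs12785878	NADSYN1/DHCR7	11	T	G	0.0361	0.0022	-0.0097	0.016
rs17216707	CYP24A1	20	T	C	0.0262	0.0027	0.0138	0.0173
rs3755967	GC	4	C	T	0.0893	0.0023	-0.0154	0.0148
rs8018720	SEC23A	14	G	C	0.0164	0.0029	-0.0163	0.0176
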