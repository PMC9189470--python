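SNP	effect_allele	other_allele	eaf	beta	se	pval	samplesize
rs0000001	A	G	0.195771096841	0.0098236079454	0.0116787396978	0.400262178239	201000
rs0000002	A	C	0.184192941532	-0.0181261851754	0.0119544578002	0.129451105882	201000
rs0000003	T	G	0.204759483952	-0.0196238837013	0.0114838851886	0.0874844418454	201000
rs0000004	T	C	0.117091455277	-0.0358219621294	0.0144125106939	0.012937799041	201000
rs0000005	A	G	0.291567524144	-0.0134038909601	0.0101962693361	0.18864848288	201000
rs0000006	A	C	0.30192058573	-0.018878549824	0.0100939541115	0.0614445421126	201000
rs0000007	T	G	0.443111820279	-0.00413128732276	0.00932866369641	0.657867364435	201000
rs0000008	T	C	0.353341079169	0.0116094918389	0.00969449971479	0.23109853106	201000
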