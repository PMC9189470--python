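SNP	effect_allele	other_allele	eaf	beta	se	pval	samplesize
rs0000001	A	G	0.195771096841	0.0026515349046	0.0201429562597	0.895272338427	7827
rs0000002	A	C	0.184192941532	0.136878332205	0.0206185022366	3.1664071376e-11	7827
rs0000003	T	G	0.204759483952	0.0964568412896	0.0198068801113	1.11674260275e-06	7827
rs0000004	T	C	0.117091455277	0.230253172905	0.0248580394813	1.99280937072e-20	7827
rs0000005	A	G	0.291567524144	0.064842667414	0.0175860591608	0.000226768072414	7827
rs0000006	A	C	0.30192058573	0.0690038358359	0.0174095905395	7.38424420341e-05	7827
rs0000007	T	G	0.443111820279	-0.0342364679214	0.0160896526218	0.0333490037564	7827
rs0000008	T	C	0.353341079169	-0.111646773285	0.0167206298597	2.4357198396e-11	7827
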