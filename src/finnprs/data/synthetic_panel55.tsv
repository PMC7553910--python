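rsid	chrom	pos	effect_allele	other_allele	eaf	or	pvalue
rs29254399	1	31075283	C	G	0.073	0.868	2.926e-18
rs45036073	1	82564798	C	G	0.100	1.172	9.044e-29
rs68962815	2	49832214	C	G	0.142	0.872	4.205e-15
rs29152483	2	151210592	A	T	0.061	1.170	1.419e-14
rs65668957	2	225256707	C	G	0.123	1.112	6.568e-22
rs70364948	2	226881457	G	A	0.099	1.161	1.538e-13
rs16777422	3	14584272	C	T	0.072	1.140	4.233e-26
rs11353114	3	90610891	T	G	0.078	1.130	2.317e-12
rs66057851	3	111609461	G	C	0.080	1.130	8.478e-28
rs41280461	3	161830758	G	A	0.131	1.110	1.240e-25
rs55411907	3	180646564	C	G	0.104	1.143	2.699e-21
rs74098762	3	181623820	G	C	0.137	1.166	3.112e-16
rs12367362	4	96636704	T	A	0.086	1.106	1.789e-20
rs40677368	4	115514205	C	G	0.102	1.174	1.130e-25
rs84136651	5	139798742	A	G	0.065	0.855	1.092e-26
rs4342563	5	144143048	A	G	0.094	1.179	7.883e-21
rs31616108	5	183385818	C	A	0.055	1.175	1.539e-10
rs41517085	6	132363178	T	C	0.110	1.170	2.757e-11
rs82244008	7	44826223	T	G	0.134	1.130	3.115e-29
rs19391775	7	130138818	A	T	0.102	1.120	3.107e-14
rs33619750	7	147705233	C	T	0.128	0.870	6.304e-19
rs43932629	7	234572385	A	T	0.114	1.125	1.135e-09
rs54578701	8	77332610	C	A	0.142	1.171	9.395e-20
rs38503049	8	97290625	A	G	0.144	1.136	1.504e-14
rs38538291	9	29900285	G	T	0.067	1.167	2.274e-12
rs42061482	10	71352249	A	C	0.142	1.169	1.043e-26
rs3537216	10	150220580	C	G	0.082	1.174	1.330e-15
rs17627303	10	200926851	A	T	0.137	1.107	1.439e-10
rs21097282	11	49808029	C	G	0.128	1.164	7.504e-17
rs71372155	11	98909999	G	A	0.057	1.164	5.812e-11
rs93478709	11	132059295	T	C	0.128	1.108	1.664e-20
rs87501532	11	191530152	T	C	0.142	1.145	2.734e-12
rs1022793	11	195767709	T	A	0.138	0.862	2.673e-28
rs20890051	12	202537116	C	T	0.068	1.167	6.214e-23
rs16408037	12	239917325	A	G	0.120	1.161	2.854e-27
rs7173623	13	79318654	C	T	0.116	1.116	9.245e-25
rs68951083	14	6359325	T	C	0.099	1.109	3.476e-23
rs78918177	14	80571093	G	T	0.051	1.160	7.822e-10
rs49309319	14	133854382	C	G	0.143	0.877	3.992e-16
rs58227040	15	71692327	G	T	0.102	1.122	8.855e-17
rs11684970	17	208351810	T	G	0.075	1.129	3.696e-26
rs53579609	17	224752638	C	T	0.109	1.155	8.060e-27
rs39978284	18	155476462	A	C	0.049	0.874	3.454e-16
rs45393475	18	185534335	T	A	0.057	1.154	8.109e-25
rs88392306	18	234331105	G	T	0.070	1.154	1.684e-20
rs87484736	19	56449221	A	C	0.107	1.160	5.490e-25
rs44335760	20	128268709	T	A	0.092	1.157	8.542e-21
rs83240961	20	197784194	C	T	0.110	1.106	5.105e-28
rs83530579	21	33844348	G	A	0.084	1.153	9.031e-15
rs4687896	21	38652631	C	A	0.138	0.889	2.708e-15
rs79511619	21	150118857	C	T	0.144	1.165	3.069e-27
rs95198832	21	207887451	C	T	0.091	1.117	2.110e-11
rs55266789	22	17961561	A	G	0.050	1.139	8.404e-11
rs8953304	22	84275571	C	G	0.059	1.124	6.030e-23
rs81722891	22	216949730	G	C	0.047	1.109	7.270e-20
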