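proband	gene	chrom	pos	ref	alt	hgvs_c	hgvs_p	exac_af	sift	polyphen2	provean	mutation_taster2	conservation
4	HCN1	5	45396665	G	T	c.1159G>T	p.Ala387Ser	.	NA	NA	NA	NA	.
8	SCN1A	2	166866266	C	G	c.3965C>G	p.Arg1322Thr	.	NA	NA	NA	NA	.
10	TCF4	18	52901827	TC	T	c.958delC	p.Gln320Serfs*8	.	NA	NA	NA	NA	.
11	GRIN2B	12	13764782	C	A	c.1657C>A	p.Pro553Thr	.	NA	NA	NA	NA	.
17	SLC6A1	3	11067528	G	A	c.919G>A	p.Gly307Arg	.	NA	NA	NA	NA	.
3	AGAP6	10	51748528	A	AC	c.53insC	p.Asp18Alafs*10	.	NA	NA	B	P	405
8	MGRN1	16	4723583	C	T	c.880C>T	p.Arg294Cys	0.000077	P	P	P	P	573
8	BTBD9	6	38256093	C	T	c.1409C>T	p.Ala470Val	.	B	P	P	P	512
11	SEMA6B	19	4555540	G	A	c.508G>A	p.Gly170Ser	.	P	P	P	P	510
12	VASH2	1	213161902	A	C	c.1044A>C	p.Glu348Asp	.	B	B	B	B	473
13	CHRNA5	15	78882481	C	A	c.748C>A	p.Pro250Thr	.	B	P	P	P	519
14	ZNF620	3	40557941	G	A	c.856G>A	p.Gly286Ser	.	P	P	P	P	317
14	GRAMD1A	19	35506764	G	A	c.1106G>A	p.Arg369His	.	P	P	P	P	358
14	NOC3L	10	96097586	G	A	c.2137G>A	p.Ala713Thr	.	B	B	B	B	0
14	GPATCH2	1	217784371	G	A	c.878G>A	p.Gly293Asp	.	B	P	P	P	304
19	GABBR2	9	101133817	G	A	c.1699G>A	p.Ala567Thr	.	P	P	P	P	412
19	ATP8B1	18	55328507	C	T	c.2606C>T	p.Thr869Ile	.	P	P	P	P	361
20	HAP1	17	39890655	G	A	c.232G>A	p.Ala78Thr	.	P	B	B	B	0
21	PDLIM7	5	176910933	G	A	c.1222G>A	p.Asp408Asn	.	P	P	B	P	515
21	SRRM3	7	75890878	C	G	c.655C>G	p.Ser218Cys	.	P	P	P	P	491
22	ANKRD31	5	74518166	A	T	c.196A>T	p.Ile66Phe	.	P	P	B	B	401
23	CACNA1I	22	40066855	C	T	c.4435C>T	p.Leu1479Phe	.	B	P	B	P	695
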