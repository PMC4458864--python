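locus	snp	ea	nea	or_exposure	p_exposure	or_outcome	p_outcome	pleiotropic	cluster
ADCY5	rs11717195	T	C	1.11	6.5E-14	1.00	8.3E-01	No	BC
CDKAL1	rs7756992	G	A	1.17	7.0E-35	1.02	7.2E-02	No	BC
CDKN2A/B	rs10811661	T	C	1.18	3.7E-27	1.00	6.8E-01	No	BC
DGKB	rs17168486	T	C	1.11	5.9E-11	1.00	6.6E-01	No	BC
HHEX/IDE	rs1111875	C	T	1.11	2.0E-19	1.02	1.3E-02	No	BC
PROX1	rs2075423	G	T	1.07	8.1E-09	1.00	7.1E-01	No	BC
SLC30A8	rs3802177	G	A	1.14	1.3E-21	1.01	3.3E-01	No	BC
THADA	rs10203174	C	T	1.14	9.5E-12	1.01	5.9E-01	No	BC
MTNR1B	rs10830963	G	C	1.10	5.3E-13	1.01	2.6E-01	No	HG
ANK1	rs516946	C	T	1.09	2.5E-10	1.01	2.8E-01	No	NA
BCAR1	rs7202877	T	G	1.12	3.5E-08	1.07	2.7E-05	No	NA
HMG20A	rs7177055	A	G	1.08	4.6E-09	1.01	2.1E-01	No	NA
KLHDC5	rs10842994	C	T	1.10	6.1E-10	0.99	2.4E-01	No	NA
TLE1	rs2796441	G	A	1.07	5.4E-09	1.02	9.5E-02	No	NA
UBE2E2	rs1496653	A	G	1.09	3.6E-09	1.01	5.8E-01	No	NA
ZMIZ1	rs12571751	A	G	1.08	1.0E-10	0.99	5.2E-01	No	NA
ARAP1 (CENTD2)	rs1552224	A	C	1.11	1.8E-10	0.99	3.4E-01	No	PI
BCL11A	rs243088	T	A	1.07	1.8E-08	1.02	3.8E-02	No	UC
HMGA2	rs2261181	T	C	1.13	1.2E-09	1.01	4.0E-01	No	UC
IGF2BP2	rs4402960	T	G	1.13	2.4E-23	1.02	1.5E-02	No	UC
JAZF1	rs849135	G	A	1.11	3.1E-17	1.02	5.8E-03	No	UC
KCNQ1	rs163184	G	T	1.09	1.2E-11	1.02	2.2E-02	No	UC
PRC1	rs12899811	G	A	1.08	6.3E-09	1.01	1.4E-01	No	UC
TSPAN8/LGR5	rs7955901	C	T	1.07	6.5E-09	0.99	4.6E-01	No	UC
WFS1	rs4458523	G	T	1.10	2.0E-15	1.01	4.6E-01	No	UC
ZBED3	rs6878122	G	A	1.10	5.0E-11	1.02	3.8E-01	No	UC
TCF7L2	rs7903146	T	C	1.39	1.2E-139	1.03	5.7E-03	Yes	BC
IRS1	rs2943640	C	A	1.10	2.7E-14	1.03	5.2E-04	Yes	IR
PPARG	rs1801282	C	G	1.13	1.1E-12	1.00	7.8E-01	Yes	IR
ANKRD55	rs459193	G	A	1.08	6.0E-09	1.02	2.5E-02	Yes	NA
CILP2	rs10401969	C	T	1.13	7.0E-09	0.93	7.3E-05	Yes	NA
FTO	rs9936385	C	T	1.13	2.6E-23	1.03	4.2E-03	Yes	NA
GRB14	rs13389219	C	T	1.07	1.0E-08	1.02	7.2E-02	Yes	NA
MC4R	rs12970134	A	G	1.08	1.2E-08	1.03	1.8E-03	Yes	NA
SPRY2	rs1359790	G	A	1.08	1.4E-08	0.99	4.7E-01	Yes	NA
ADAMTS9	rs6795735	C	T	1.08	7.4E-11	0.98	1.8E-02	Yes	UC
KCNJ11	rs5215	C	T	1.07	8.5E-10	1.02	1.8E-02	Yes	UC
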