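locus	snp	ea	nea	effect_fg	or_fg	p_exposure	or_outcome	p_outcome	pleiotropic
ADCY5	rs11708067	A	G	0.02	1.02	1.3E-18	1.00	7.0E-01	No
ADRA2A	rs11195502	C	T	0.03	1.03	2.0E-18	1.02	2.8E-01	No
ARAP1	rs11603334	G	A	0.02	1.02	1.1E-11	0.99	4.0E-01	No
CDKAL1	rs9368222	A	C	0.01	1.01	1.0E-09	1.02	5.3E-02	No
CDKN2B	rs10811661	T	C	0.02	1.02	5.7E-18	1.00	6.8E-01	No
CRY2	rs11607883	G	A	0.02	1.02	6.3E-24	1.00	8.1E-01	No
DGKB/TMEM195	rs2191349	T	G	0.03	1.03	1.3E-42	1.01	4.3E-01	No
DNLZ	rs3829109	G	A	0.02	1.02	1.1E-10	1.00	9.5E-01	No
FOXA2	rs6113722	G	A	0.04	1.04	2.5E-11	1.00	8.8E-01	No
G6PC2	rs560887	C	T	0.07	1.07	1.4E-178	1.02	1.5E-01	No
GCK	rs2908289	A	G	0.06	1.06	3.3E-88	1.00	9.8E-01	No
GLIS3	rs10814916	C	A	0.02	1.02	2.3E-13	0.99	1.7E-01	No
GRB10	rs6943153	T	C	0.02	1.02	1.6E-12	0.99	1.7E-01	No
IGF2BP2	rs7651090	G	A	0.01	1.01	1.8E-08	1.02	1.8E-02	No
IKBKAP	rs16913693	T	G	0.04	1.04	3.5E-11	1.03	3.5E-01	No
KL	rs576674	G	A	0.02	1.02	2.3E-08	1.02	3.9E-01	No
MADD	rs11039182	T	C	0.02	1.02	4.8E-22	1.00	8.9E-01	No
MTNR1B	rs10830963	G	C	0.08	1.08	1.1E-215	1.01	2.6E-01	No
PCSK1/MIR583	rs4869272	T	C	0.02	1.02	1.0E-15	0.99	5.8E-01	No
PDX1	rs11619319	G	A	0.02	1.02	1.3E-15	1.01	3.4E-01	No
PROX1	rs340874	C	T	0.01	1.01	4.1E-10	1.00	8.7E-01	No
SLC30A8	rs11558471	A	G	0.03	1.03	7.8E-37	1.01	2.2E-01	No
VPS13C/C2CD4A/B	rs4502156	T	C	0.02	1.02	1.4E-25	0.99	5.0E-01	No
WARS	rs3783347	G	T	0.02	1.02	1.3E-10	1.02	1.7E-01	No
AMT	rs11715915	C	T	0.01	1.01	4.9E-08	1.05	6.3E-06	Yes
FADS1	rs174576	C	A	0.02	1.02	1.2E-18	1.02	8.9E-02	Yes
GCKR	rs780094	C	T	0.03	1.03	2.6E-37	1.01	5.4E-01	Yes
GIPR	rs2302593	C	G	0.01	1.01	9.3E-10	1.03	1.2E-01	Yes
P2RX2	rs10747083	A	G	0.01	1.01	7.6E-09	1.02	4.2E-01	Yes
PPP1R3B/LOC157273	rs983309	T	G	0.03	1.03	6.3E-15	1.00	7.9E-01	Yes
SLC2A2	rs1280	T	C	0.03	1.03	8.6E-18	1.01	6.4E-01	Yes
TCF7L2	rs7903146	T	C	0.02	1.02	2.7E-20	1.03	5.7E-03	Yes
TOP1	rs6072275	A	G	0.02	1.02	1.7E-08	0.99	3.4E-01	Yes
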