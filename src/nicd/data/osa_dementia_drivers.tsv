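common_gene	dementia_genes	osa_genes	olfactory	gpcr	p_value
TMEM181	SH3RF1	NRG1	0	0	1.36e-4
TSPAN19	TSPAN16	TSPAN18	0	0	8.31e-6
CSTL1	AHSG,PRKN	NRG1	0	0	4.93e-4
RNF121	ITGB2	LPAR1	0	0	2.60e-4
AL121594.3	RNF4	NRG1	0	0	5.04e-4
OR4E2	MC1R	ARRB1	1	1	5.15e-4
FAM241A	PLP1,LINGO1	LPAR1,SGCD	0	0	2.35e-4
FITM2	CCRL2,HTR2C	LPAR1,TSPAN18	0	0	2.74e-4
OR2L13	ZP3	ARRB1	1	1	2.02e-4
OR11H4	PTAFR	ARRB1	1	0	2.13e-4
CST11	CST3,AHSG	NRG1	0	0	3.43e-4
OR4C6	HEATR4	ARRB1	1	1	2.71e-4
TMEM120A	VKORC1	TSPAN18	0	0	2.47e-4
OR2AE1	PTAFR,GPR65	ARRB1	1	1	4.74e-4
OR7C1	CHRM1	ARRB1	1	1	3.63e-4
TMEM87B	SLC30A7	LPAR1	0	0	1.91e-4
OR8D1	CBLL2,ADAD1	ARRB1	1	1	2.88e-4
OR4S2	ADAM10	ARRB1	1	1	3.57e-4
OR2J2	PCDH11X	ARRB1	1	1	5.26e-4
TMED8	TMED9	PTGER3	0	0	1.22e-4
OR2C3	CBLL2,ADAD1,CCDC62	ARRB1	0	0	4.16e-4
TMCO5A	DKKL1,TEX33,ADAD1,CCDC62,CBLL2	TSPAN18	0	0	3.38e-4
HSPA7	UBXN11	ARRB1	0	0	2.27e-4
ZSWIM9	ESR2,ZNF292	AHDC1	0	0	5.15e-4
FABP9	FABP2	FABP4	0	0	6.09e-5
GTSF1	HSPB1	MPHOSPH6	0	0	1.47e-4
TMEM151A	CAMK2A,SNCB	LPAR1	0	0	5.60e-4
TMEM218	NARS2	TSPAN18	0	0	3.99e-4
MGAT5B	FAM171A2,MGAT5	PTGER3	0	0	2.44e-4
OR6F1	PTAFR	ARRB1	1	1	2.13e-4
ZNF385D	ZNF804A	PTGER3	0	0	4.71e-5
TMEM161B	RPS6KB1	LPAR1	0	0	1.63e-4
LARGE2	DKKL1	NRG1	0	0	4.13e-4
SCFD2	SCFD1,STXBP2,UBE2Z,SIRT2	NBAS	0	0	2.83e-4
RAVER2	CNKSR3	NRG1	0	0	2.94e-4
CPNE8	TRPM1,VAMP8,NDUFS1,SOAT1	ARRB1	0	0	5.29e-4
ARRDC2	RXRA,PDE4D	ARRB1	0	0	4.68e-4
OLFM2	TUBB1	NBAS	0	0	3.55e-4
ENOX1	NOX4,SETD1A,RBMS3	LPAR1	0	0	5.76e-4
TMEM120B	RNF5,SIGMAR1	LPAR1	0	0	4.32e-4
BLOC1S3	DTNBP1,DNAJC6	ARRB1	0	0	2.63e-4
CFAP45	SPTAN1,PACRG	ARRB1	0	0	4.13e-4
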