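uniprot	gene_symbol	gene_id	mean_ratio	sd_ratio	p_printed	call	description
1433B	Ywhab	54401	0.99	0.375	0.909	ns	14-3-3 protein beta/alpha
AATM	Got2	14719	1.07	0.537	0.865	ns	Aspartate aminotransferase, mitochondrial
ACTB	Actb	11461	0.97	0.110	0.560	ns	Actin, cytoplasmic 1
ACTC	Actc1	11464	0.99	0.124	0.758	ns	Actin, alpha cardiac muscle 1
ADT1	Slc25a4	11739	0.90	0.240	0.485	ns	ADP/ATP translocase 1
ADT2	Slc25a5	11740	0.95	0.254	0.712	ns	ADP/ATP translocase 2
ANS1B	Anks1b	77531	1.05	0.099	0.588	ns	Ankyrin repeat and sterile alpha motif domain-containing protein 1B
AT1A3	Atp1a3	232975	1.08	0.021	0.180	ns	Sodium/potassium-transporting ATPase subunit alpha-3
AT1B1	Atp1b1	11931	1.22	0.601	0.591	ns	Sodium/potassium-transporting ATPase subunit beta-1
ATPA	Atp5a1	11946	0.92	0.121	0.304	ns	ATP synthase subunit alpha, mitochondrial
ATPB	Atp5b	11947	0.91	0.164	0.366	ns	ATP synthase subunit beta, mitochondrial
BAIP2	Baiap2	108100	1.29	0.335	0.237	ns	Brain-specific angiogenesis inhibitor 1-associated protein 2
BASP1	Basp1	70350	1.13	0.070	0.101	ns	Brain acid soluble protein 1
BSN	Bsn	12217	1.13	0.112	0.204	ns	Protein bassoon
C1QBP	C1qbp	12261	0.99	0.217	0.886	ns	Complement component 1 Q subcomponent-binding protein, (mito)
CA2D1	Cacna2d1	12293	0.99	0.111	0.736	ns	Voltage-dependent calcium channel subunit alpha-2/delta-1
CA2D3	Cacna2d3	12294	0.79	0.137	0.065	ns	Voltage-dependent calcium channel subunit alpha-2/delta-3
CAD13	Cdh13	12554	0.93	0.130	0.376	ns	Cadherin-13
CALM	Calm1	12313	0.85	0.169	0.186	ns	Calmodulin
CLH1	Cltc	67300	0.92	0.205	0.479	ns	Clathrin heavy chain 1
CN37	Cnp	12799	1.32	0.244	0.101	ns	2',3'-cyclic-nucleotide 3'-phosphodiesterase
CNTN1	Cntn1	12805	0.89	0.125	0.203	ns	Contactin-1
CNTN2	Cntn2	21367	0.88	0.222	0.363	ns	Contactin-2
COX2	Mtco2	17709	1.04	0.158	0.776	ns	Cytochrome c oxidase subunit 2
COX5A	Cox5a	12858	1.02	0.491	0.974	ns	Cytochrome c oxidase subunit 5A, mitochondrial
CSPG2	Vcan	13003	0.82	0.079	0.031	significant	Versican core protein
DLG4	Dlg4	13385	0.94	0.236	0.631	ns	Disks large homolog 4
ENPP6	Enpp6	320981	1.22	0.340	0.366	ns	Ectonucleotide pyrophosphatase/phosphodiesterase 6
ERC2	Erc2	238988	1.17	0.066	0.042	significant	ERC protein 2
FLOT1	Flot1	14251	0.80	0.146	0.084	ns	Flotillin-1
FLOT2	Flot2	14252	1.10	0.101	0.280	ns	Flotillin-2
GBB1	Gnb1	14688	0.76	0.264	0.186	ns	Guanine nucleotide-binding protein G(I)/G(S)/G(T) subunit beta-1
GBG12	Gng12	14701	1.29	0.860	0.608	ns	Guanine nucleotide-binding protein G(I)/G(S)/G(O) subunit gamma-12
GBG2	Gng2	14702	1.28	0.226	0.121	ns	Guanine nucleotide-binding protein G(I)/G(S)/G(O) subunit gamma-2
GNAO	Gnao1	14681	1.19	0.229	0.259	ns	Guanine nucleotide-binding protein G(o) subunit alpha
GNAS1	Gnas	14683	1.14	0.361	0.581	ns	Guanine nucleotide-binding protein G(s) subunit alpha isoforms XLas
GNAZ	Gnaz	14687	1.12	0.251	0.516	ns	Guanine nucleotide-binding protein G(z) subunit alpha
HOME1	Homer1	26556	1.31	0.280	0.148	ns	Homer protein homolog 1
HSP7C	Hspa8	15481	1.01	0.064	>0.999	ns	Heat shock cognate 71 kDa protein
IGS21	Igsf21	230868	1.01	0.083	0.918	ns	Immunoglobulin superfamily member 21
KCC2A	Camk2a	12322	1.27	0.299	0.215	ns	Calcium/calmodulin-dependent protein kinase type II subunit alpha
KCC2B	Camk2b	12323	1.24	0.365	0.343	ns	Calcium/calmodulin-dependent protein kinase type II subunit beta
KCC2G	Camk2g	12325	1.21	0.331	0.362	ns	Calcium/calmodulin-dependent protein kinase type II subunit gamma
KCRB	Ckb	12709	0.85	0.124	0.108	ns	Creatine kinase B-type
LSAMP	Lsamp	268890	0.94	0.142	0.443	ns	Limbic system-associated membrane protein
LY6H	Ly6h	23934	0.76	0.020	0.003	significant	Lymphocyte antigen 6H
MAP1A	Map1a	17754	1.06	0.097	0.499	ns	Microtubule-associated protein 1A
MBP	Mbp	17196	1.35	0.318	0.144	ns	Myelin basic protein
MDHM	Mdh2	17448	0.85	0.327	0.444	ns	Malate dehydrogenase, mitochondrial
MOBP	Mobp	17433	1.47	0.345	0.089	ns	Myelin-associated oligodendrocyte basic protein
MOG	Mog	17441	1.31	0.185	0.060	ns	Myelin-oligodendrocyte glycoprotein
MYH10	Myh10	77579	1.02	0.245	0.966	ns	Myosin-10
MYH9	Myh9	17886	1.14	0.668	0.760	ns	Myosin-9
MYO5A	Myo5a	17918	1.05	0.136	0.720	ns	Unconventional myosin-Va
MYPR	Plp1	18823	1.55	0.176	0.008	significant	Myelin proteolipid protein
NCAM1	Ncam1	17967	1.00	0.128	0.880	ns	Neural cell adhesion molecule 1
NCAN	Ncan	13004	1.02	0.427	0.990	ns	Neurocan core protein
NEGR1	Negr1	320840	1.01	0.209	0.980	ns	Neuronal growth regulator 1
NTRI	Ntm	235106	0.97	0.101	0.566	ns	Neurotrimin
ODO2	Dlst	78920	1.15	0.267	0.448	ns	Dihydrolipoyllysine succinyltransferase comp. of 2-oxoglutarate dehydrogenase complex
ODP2	Dlat	235339	1.03	0.150	0.894	ns	Dihydrolipoyllysine acetyltransferase comp. of pyruvate dehydrogenase complex
OMGP	Omg	18377	1.12	0.044	0.076	ns	Oligodendrocyte-myelin glycoprotein
PCLO	Pclo	26875	1.08	0.015	0.140	ns	Protein piccolo
PRIO	Prnp	19122	0.84	0.142	0.126	ns	Major prion protein
RAC1	Rac1	19353	1.28	0.381	0.293	ns	Ras-related C3 botulinum toxin substrate 1
SCAI	Scai	320271	1.46	0.971	0.471	ns	Protein SCAI
SEPT7	Sept7	235072	1.45	0.272	0.052	ns	Septin-7
SHAN3	Shank3	58234	1.01	0.284	0.970	ns	SH3 and multiple ankyrin repeat domains protein 3
SNP25	Snap25	20614	1.10	0.551	0.800	ns	Synaptosomal-associated protein 25
SPTA2	Sptan1	20740	0.97	0.157	0.681	ns	Spectrin alpha chain, brain
SPTB2	Sptbn1	20742	0.97	0.099	0.530	ns	Spectrin beta chain, brain 1
STX1B	Stx1b	56216	1.05	0.445	0.895	ns	Syntaxin-1B
SYGP1	Syngap1	240057	1.09	0.106	0.344	ns	Ras GTPase-activating protein SynGAP
SYT1	Syt1	20979	0.90	0.236	0.456	ns	Synaptotagmin-1
TBA1B	Tuba1b	22143	1.21	0.155	0.113	ns	Tubulin alpha-1B chain
TBB2A	Tubb2a	22151	1.29	0.155	0.045	significant	Tubulin beta-2A chain
TBB5	Tubb5	22154	1.27	0.125	0.034	significant	Tubulin beta-5 chain
THY1	Thy1	21838	0.66	0.132	0.014	significant	Thy-1 membrane glycoprotein
VA0D1	Atp6v0d1	11972	1.27	0.255	0.163	ns	V-type proton ATPase subunit d 1
VAMP2	Vamp2	22318	1.12	0.715	0.810	ns	Vesicle-associated membrane protein 2
VATA	Atp6v1a	11964	1.05	0.137	0.697	ns	V-type proton ATPase catalytic subunit A
VATB2	Atp6v1b2	11966	1.04	0.090	0.662	ns	V-type proton ATPase subunit B, brain isoform
VATE1	Atp6v1e1	11973	1.17	0.232	0.314	ns	V-type proton ATPase subunit E 1
VDAC1	Vdac1	22333	1.00	0.367	0.954	ns	Voltage-dependent anion-selective channel protein 1
VPP1	Atp6v0a1	11975	1.19	0.156	0.144	ns	V-type proton ATPase 116 kDa subunit a isoform 1
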