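uniprot	gene_symbol	gene_id	description
1433B	Ywhab	54401	14-3-3 protein beta/alpha
1433E	Ywhae	22627	14-3-3 protein epsilon
1433G	Ywhag	22628	14-3-3 protein gamma
1433Z	Ywhaz	22631	14-3-3 protein zeta/delta
AATM	Got2	14719	Aspartate aminotransferase, mitochondrial
ACTB	Actb	11461	Actin, cytoplasmic 1
ACTC	Actc1	11464	Actin, alpha cardiac muscle 1
ACTN1	Actn1	109711	Actinin-1
ACTN2	Actn2	11472	Actinin-2
ADT1	Slc25a4	11739	ADP/ATP translocase 1
ADT2	Slc25a5	11740	ADP/ATP translocase 2
AGK	Agk	69923	Acylglycerol kinase, mitochondrial
AINX	Ina	226180	Alpha-internexin
ALDOA	Aldoa	11674	Fructose-bisphosphate aldolase A
ANS1B	Anks1b	77531	Ankyrin repeat and sterile alpha motif domain-containing protein 1B
AT1A1	Atp1a1	11928	Na/K-transporting ATPase subunit alpha-1
AT1A3	Atp1a3	232975	Na/K-transporting ATPase subunit alpha-3
AT1B1	Atp1b1	11931	Sodium/potassium-transporting ATPase subunit beta-1
ATPA	Atp5a1	11946	ATP synthase subunit alpha, mitochondrial
ATPB	Atp5b	11947	ATP synthase subunit beta, mitochondrial
BAIP2	Baiap2	108100	Brain-specific angiogenesis inhibitor 1-assoc. protein 2
BASP1	Basp1	70350	Brain acid soluble protein 1
BSN	Bsn	12217	Protein bassoon
C1QBP	C1qbp	12261	Complement component 1 Q subcomponent-binding protein (mito)
CA2D1	Cacna2d1	12293	Voltage-dependent Ca channel subunit alpha-2/delta-1
CA2D2	Cacna2d2	56808	Voltage-dependent Ca channel subunit alpha-2/delta-2
CA2D3	Cacna2d3	12294	Voltage-dependent Ca channel subunit alpha-2/delta-3
CAD13	Cdh13	12554	Cadherin-13
CALM	Calm1	12313	Calmodulin
CLCB	Cltb	74325	Clathrin light chain B
CLCN6	Clcn6	26372	Chloride transport protein 6
CLD11	Cldn11	18417	Claudin-11
CLH1	Cltc	67300	Clathrin heavy chain 1
CMC1	Slc25a12	78830	Calcium-binding mitochondrial carrier protein Aralar1
CN37	Cnp	12799	2',3'-cyclic-nucleotide 3'-phosphodiesterase
CNTN1	Cntn1	12805	Contactin-1
CNTN2	Cntn2	21367	Contactin-2
CNTP1	Cntnap1	53321	Contactin-associated protein 1
COX2	Mtco2	17709	Cytochrome c oxidase subunit 2
COX5A	Cox5a	12858	Cytochrome c oxidase subunit 5A, mitochondrial
CSPG2	Vcan	13003	Versican core protein
CTNA2	Ctnna2	12386	Catenin alpha-2
DLG4	Dlg4	13385	Disks large homolog 4
DLGP3	Dlgap3	242667	Disks large-associated protein 3
DPYL2	Dpysl2	12934	Dihydropyrimidinase-related protein 2
DYL1	Dynll1	56455	Dynein light chain 1, cytoplasmic
ENPP6	Enpp6	320981	Ectonucleotide pyrophosphatase/phosphodiesterase member 6
ERC2	Erc2	238988	ERC protein 2
FLOT1	Flot1	14251	Flotillin-1
FLOT2	Flot2	14252	Flotillin-2
G3P	Gapdh	14433	Glyceraldehyde-3-phosphate dehydrogenase
GBB1	Gnb1	14688	Guanine nucleotide-binding protein G(I)/G(S)/G(T) subunit beta-1
GBG12	Gng12	14701	Guanine nucleotide-binding protein G(I)/G(S)/G(O) subunit gamma12
GBG2	Gng2	14702	Guanine nucleotide-binding protein G(I)/G(S)/G(O) subunit gamma2
GNAI1	Gnai1	14677	Guanine nucleotide-binding protein G(i) subunit alpha1
GNAI2	Gnai2	14678	Guanine nucleotide-binding protein G(i) subunit alpha2
GNAO	Gnao1	14681	Guanine nucleotide-binding protein G(o) subunit alpha
GNAS1	Gnas	14683	Guanine nucleotide-binding protein G(s) subunit alpha isoforms XLas
GNAZ	Gnaz	14687	Guanine nucleotide-binding protein G(z) subunit alpha
HOME1	Homer1	26556	Homer protein homolog 1
HPLN1	Hapln1	12950	Hyaluronan and proteoglycan link protein 1
HPLN2	Hapln2	73940	Hyaluronan and proteoglycan link protein 2
HS71L	Hspa1l	15482	Heat shock 70 kDa protein 1-like
HSP7C	Hspa8	15481	Heat shock cognate 71 kDa protein
HXK1	Hk1	15275	Hexokinase-1
IGS21	Igsf21	230868	Immunoglobulin superfamily member 21
IQEC1	Iqsec1	232227	IQ motif and SEC7 domain-containing protein 1
IQEC2	Iqsec2	245666	IQ motif and SEC7 domain-containing protein 2
KCC2A	Camk2a	12322	Ca/calmodulin-dependent protein kinase type II α sub.
KCC2B	Camk2b	12323	Ca/calmodulin-dependent protein kinase type II β sub.
KCC2D	Camk2d	108058	Ca/calmodulin-dependent protein kinase type II δ sub.
KCC2G	Camk2g	12325	Ca/calmodulin-dependent protein kinase type II γ sub.
KCRB	Ckb	12709	Creatine kinase B-type
LSAMP	Lsamp	268890	Limbic system-associated membrane protein
LY6H	Ly6h	23934	Lymphocyte antigen 6H
MAP1A	Map1a	17754	Microtubule-associated protein 1A
MBP	Mbp	17196	Myelin basic protein
MDHM	Mdh2	17448	Malate dehydrogenase, mitochondrial
ML12B	Myl12b	67938	Myosin regulatory light chain 12B
MOBP	Mobp	17433	Myelin-associated oligodendrocyte basic protein
MOG	Mog	17441	Myelin-oligodendrocyte glycoprotein
MYH10	Myh10	77579	Myosin-10
MYH9	Myh9	17886	Myosin-9
MYL6	Myl6	17904	Myosin light polypeptide 6
MYO5A	Myo5a	17918	Unconventional myosin-Va
MYPR	Plp1	18823	Myelin proteolipid protein
NCAM1	Ncam1	17967	Neural cell adhesion molecule 1
NCAN	Ncan	13004	Neurocan core protein
NDUA4	Ndufa4	17992	NADH dehydrogenase 1 alpha subcomplex sub. 4
NEGR1	Negr1	320840	Neuronal growth regulator 1
NEUM	Gap43	14432	Neuromodulin
NFL	Nefl	18039	Neurofilament light polypeptide
NFM	Nefm	18040	Neurofilament medium polypeptide
NTRI	Ntm	235106	Neurotrimin
ODO2	Dlst	78920	Dihydrolipoyllysine-residue succinyltransferase component of 2-oxoglutarate dehydrogenase complex (mito)
ODP2	Dlat	235339	Dihydrolipoyllysine-residue acetyltransferase component of pyruvate dehydrogenase complex (mito)
OMGP	Omg	18377	Oligodendrocyte-myelin glycoprotein
PCLO	Pclo	26875	Protein piccolo
PRIO	Prnp	19122	Major prion protein
RAC1	Rac1	19353	Ras-related C3 botulinum toxin substrate 1
SCAI	Scai	320271	Protein SCAI
SEPT7	Sept7	235072	Septin-7
SHAN3	Shank3	58234	SH3 and multiple ankyrin repeat domains protein 3
SNP25	Snap25	20614	Synaptosomal-associated protein 25
SPTA2	Sptan1	20740	Spectrin alpha chain, brain
SPTB2	Sptbn1	20742	Spectrin beta chain, brain 1
STX1B	Stx1b	56216	Syntaxin-1B
SYGP1	Syngap1	240057	Ras GTPase-activating protein SynGAP
SYPH	Syp	20977	Synaptophysin
SYT1	Syt1	20979	Synaptotagmin-1
SYT2	Syt2	20980	Synaptotagmin-2
TBA1A	Tuba1a	22142	Tubulin alpha-1A chain
TBA1B	Tuba1b	22143	Tubulin alpha-1B chain
TBA3	Tuba3a	22144	Tubulin alpha-3 chain
TBA4A	Tuba4a	22145	Tubulin alpha-4A chain
TBB2A	Tubb2a	22151	Tubulin beta-2A chain
TBB3	Tubb3	22152	Tubulin beta-3 chain
TBB4A	Tubb4a	22153	Tubulin beta-4A chain
TBB4B	Tubb4b	227613	Tubulin beta-4B chain
TBB5	Tubb5	22154	Tubulin beta-5 chain
THY1	Thy1	21838	Thy-1 membrane glycoprotein
TPM3	Tpm3	59069	Tropomyosin alpha-3 chain
VA0D1	Atp6v0d1	11972	V-type proton ATPase subunit d 1
VAMP2	Vamp2	22318	Vesicle-associated membrane protein 2
VATA	Atp6v1a	11964	V-type proton ATPase catalytic subunit A
VATB2	Atp6v1b2	11966	V-type proton ATPase subunit B, brain isoform
VATC1	Atp6v1c1	66335	V-type proton ATPase subunit C 1
VATD	Atp6v1d	73834	V-type proton ATPase subunit D
VATE1	Atp6v1e1	11973	V-type proton ATPase subunit E 1
VATF	Atp6v1f	66144	V-type proton ATPase subunit F
VATG2	Atp6v1g2	66237	V-type proton ATPase subunit G 2
VDAC1	Vdac1	22333	Voltage-dependent anion-selective channel protein 1
VPP1	Atp6v0a1	11975	V-type proton ATPase 116 kDa subunit a isoform 1
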