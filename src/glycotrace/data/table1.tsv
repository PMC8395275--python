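no	peptide	protein_name	short_name	ratio
1	nITISnVTK	Tenascin-R	TN-R	4.14
2	nVTVnETER	Myelin-associated glycoprotein	MAG	2.44
3	VLTLAnFTTK	Thy-1 membrane glycoprotein	Thy1	3.63
4	LLFPTnSSSR	Neural cell adhesion molecule L1	L1CAM	WT only
5	TGDGSnVTSnFTK	Receptor-type tyrosine-protein phosphatase eta	R-PTP-eta	WT only
6	nSTTTDQnFTSAK	Leukocyte surface antigen CD47	CD47	12.68
7	DTIPGDPSSnATSR	Ephrin-B3	-	WT only
8	SEMMYGnETELK	Receptor-type tyrosine-protein phosphatase zeta	R-PTP-zeta	WT only
9	VLVAPPSEEAnTTK	Excitatory amino acid transporter 2	GLT-1	4.59
10	SFSGLLDcGncSR	Voltage-dependent calcium channel subunit alpha-2/delta-1	CA2D1	WT only
11	FHVnYTQPLVAVK	Sodium/potassium-transporting ATPase subunit beta-2	AMOG	WT only
12	DGQLLPSSnYSNIK	Neural cell adhesion molecule 1	NCAM1	1.3
13	GnYScFVSSPSITK	Contactin-1	-	2.66
14	WYSAGLASnSSWFR	Prostaglandin-H2 D-isomerase	PGDS2	WT only
15	ETLqNNSFLITTVnK	Collectin-12	CL-P1	WT only
16	LSVEcAnK	Synaptophysin	-	WT only
17	HDVFcGFLLcTnLTR	Disintegrin and metalloproteinase domain-containing protein 23	ADAM23	WT only
18	TYcANEPLSncSqVNR	Sialomucin core protein 24	MUC24	WT only
19	TVVAPSTEGGLnLTSTFLR	Prostaglandin-H2 D-isomerase	PGDS2	WT only
20	FVPAATDAQAGGDnSSVQnR	Glutamate receptor 1	GluA1	WT only
21	VnGTDLAPDLLnGSQLILR	Ciliary neurotrophic factor receptor subunit alpha	CNTFR-alpha	WT only
22	ARGnGTLITFHSAFQccGK	Tetraspanin-2	Tspan-2	WT only
23	LVLIQDAPTLGnDTAAIEnR	Glutamate receptor 4	GluA4	WT only
24	nLTScPDGAPFIQHGPDYR	Sodium/potassium-transporting ATPase subunit beta-3	ATPB-3	WT only
25	HNFRPGTDFVVEYIDSnHTK	Neurofascin	-	WT only
26	YIITWDHVVALSnESTVTGYK	Contactin-1	-	2.66
27	TnASDLGnYScLATSHLDFSTK	Contactin-2	-	WT only
28	SDVPNTSPnSTSQHVAEFETER	Receptor-type tyrosine-protein phosphatase zeta	R-PTP-zeta	WT only
29	LTFFnVSEHDYGnYTcVASNK	Neurotrimin	-	3.08
30	SNPEPSVAFELPSRnVTVnETER	Myelin-associated glycoprotein	MAG	2.44
31	SYIFIYDGnKNSTTTDQnFTSAK	Leukocyte surface antigen CD47	CD47	12.68
32	HVHnDSVAHSEHGEPGHSPSPETnK	Zinc transporter ZIP10	ZIP-10	WT only
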