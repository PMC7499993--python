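row_id	dataset_id	disease	therapy	platform	platform_type	n_cases	n_responders	n_nonresponders	n_core_genes	response_rule_id
1	GSE25066	Breast cancer with different hormonal and HER2 status	Neoadjuvant taxane + anthracycline	Affymetrix Human Genome U133 Array	microarray	508	118	389	20	breast_cr_pr
2	GSE41998	Breast cancer with different hormonal and HER2 status	Neoadjuvant doxorubicin + cyclophosphamide, followed by paclitaxel	Affymetrix Human Genome U133 Array	microarray	124	90	34	11	breast_cr_pr
3	GSE20271	Breast cancer with different hormonal and HER2 status	Paclitaxel + fluorouracil + adriamycin + cyclophosphamide	Affymetrix Human Genome U133A Array	microarray	85	18	66	11	breast_cr_pr
4	GSE50948	Breast cancer with different hormonal and HER2 status	Paclitaxel + doxorubicin followed by cyclophosphamide + methotrexate/fluorouracil followed by trastuzumab	Affymetrix Human Genome U133 Plus 2.0 Array	microarray	156	53	103	19	breast_cr_pr
5	GSE9782	Multiple myeloma	Bortezomib monotherapy	Affymetrix Human Genome U133 Array	microarray	169	85	84	18	myeloma_gse9782
6	GSE39754	Multiple myeloma	Vincristine + adriamycin + dexamethasone followed by autologous stem cell transplantation (ASCT)	Affymetrix Human Exon 1.0 ST Array	microarray	136	74	62	16	myeloma_vgpr
7	GSE68871	Multiple myeloma	Bortezomib-thalidomide-dexamethasone	Affymetrix Human Genome U133 Plus	microarray	118	69	49	12	myeloma_vgpr
8	GSE55145	Multiple myeloma	Bortezomib followed by ASCT	Affymetrix Human Exon 1.0 ST Array	microarray	61	33	28	14	myeloma_vgpr
9	TARGET-50	Childhood kidney Wilms tumor	Vincristine sulfate + cyclosporine, cytarabine, daunorubicin + conventional surgery + radiation therapy	Illumina HiSeq 2000	rnaseq	122	36	86	14	target_survival
10	TARGET-10	Childhood B acute lymphoblastic leukemia	Vincristine sulfate + carboplatin, cyclophosphamide, doxorubicin	Illumina HiSeq 2000	rnaseq	98	30	68	14	target_survival
11	TARGET-20	Childhood acute myeloid leukemia	Non-target drugs (asparaginase, cyclosporine, cytarabine, daunorubicin, etoposide, methotrexate, mitoxantrone) including busulfan and cyclophosphamide	Illumina HiSeq 2000	rnaseq	54	31	23	10	target_survival
12	TARGET-20	Childhood acute myeloid leukemia	Same non-target drugs, but excluding busulfan and cyclophosphamide	Illumina HiSeq 2000	rnaseq	142	62	80	16	target_survival
13	GSE18728	Breast cancer	Docetaxel, capecitabine	Affymetrix Human Genome U133 Plus 2.0 Array	microarray	61	23	38	16	breast_cr_pr
14	GSE20181	Breast cancer	Letrozole	Affymetrix Human Genome U133A Array	microarray	52	37	15	11	breast_cr_pr
15	GSE20194	Breast cancer	Paclitaxel; (tri)fluoroacetyl chloride; 5-fluorouracil, epirubicin, cyclophosphamide	Affymetrix Human Genome U133A Array	microarray	52	11	41	10	breast_cr_pr
16	GSE23988	Breast cancer	Docetaxel, capecitabine	Affymetrix Human Genome U133A Array	microarray	61	20	41	18	breast_cr_pr
17	GSE22358	Breast cancer	Docetaxel, capecitabine	Agilent UNC Perou Lab Homo sapiens 1X44K Custom Array	microarray	122	116	6	2	breast_cr_pr
18	GSE32646	Breast cancer	Paclitaxel, 5-fluorouracil, epirubicin, cyclophosphamide	Affymetrix Human Genome U133 Plus 2.0 Array	microarray	115	27	88	17	breast_cr_pr
19	GSE37946	Breast cancer	Trastuzumab	Affymetrix Human Genome U133A Array	microarray	50	27	23	14	breast_cr_pr
20	GSE42822	Breast cancer	Docetaxel, 5-fluorouracil, epirubicin, cyclophosphamide, capecitabine	Affymetrix Human Genome U133A Array	microarray	91	38	53	13	breast_cr_pr
21	GSE5122	Acute myeloid leukemia	Tipifarnib	Affymetrix Human Genome U133A Array	microarray	57	13	44	10	stable_as_responder
22	GSE59515	Breast cancer	Letrozole	Illumina HumanHT-12 V4.0 expression beadchip	microarray	75	51	24	15	breast_cr_pr
23	GSE76360	Breast cancer	Trastuzumab	Illumina HumanHT-12 V3.0 expression beadchip	microarray	48	42	6	3	breast_cr_pr
24	TCGA-LGG	Low-grade glioma	Temozolomide + (optionally) mibefradil	Illumina HiSeq 2000	rnaseq	131	100	31	9	stable_as_responder
25	TCGA-LC	Lung cancer all types	Paclitaxel + (optionally) cisplatin/carboplatin, reolysin	Illumina HiSeq 2000	rnaseq	41	24	17	7	stable_as_responder
26	TCGA-UC	Uterine corpus endothelial carcinoma	Paclitaxel + (optionally) carboplatin, cisplatin, doxorubicin	Illumina HiSeq 2000	rnaseq	57	57	7	2	stable_as_responder
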