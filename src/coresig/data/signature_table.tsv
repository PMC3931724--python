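index	description	n_genes	pct_original
1	Differentially expressed genes by TGFb in p53-depleted MDA-MB-231 cells	105	5
2	Coculture of mesenchymal stromal cells with CD133+ hematopoietic stem cells	21	2
3	TGFb-induced EMT in HMECs predisposed to ionizing radiation	32	3
4	Trophoblast invasion-related genes	648	7
5	Overexpression of Integrin a6b4 in MDA-MB-435 cells	263	10
6	Ezrin knockdown in SW480	26	2
7	MDA-MB-231 cells with wild-type SNAIL vs dominant negative SNAIL	50	2
8	MDA-MB-435 cells with wild-type NM23-H1 vs mutant NM23-H1	44	3
9	Functional implications of non-lens bg-Cristallin and Refoil Factor Complex	55	6
10	Expression profiling of central and peripheral zones of pancreatic carcinoma	756	12
11	Normal HMECs vs HMECs transfected with constitutively active RhoA	135	2
12	Overexpression of classIIb HLH factors E2-2A and E2-2B in MDCK cells	147	5
13	Genes epigenetically regulated in poorly vs highly metastatic MDA-MB-468 variants	136	2
14	Expression profiling of migratory cells in the Drosophila ovary	33	3
15	Transfection of MIR-520C in MCF-7 cells	113	4
16	Transfection of MIR-373 in MCF-7 cells	128	7
17	Comparison of mesenchymal and epithelial cells	186	3
18	Genes differentially expressed in mesenchymal stem cells induced by CCL25	105	3
19	Genes differentially expressed across migratory glioma cell lines	89	1
20	Genes differentially expressed in MDA-MB-231 cells after CD146 downmodulation	45	3
21	Keratinocytes treated with TGFb to suppress proliferation but not migration	92	4
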