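module	symbol	gene_id	description	fc	mm	cor	significance
salmon	DNAJC2	C16211_c1_seq1_	DnaJ homolog subfamily C member 2	2.37	0.967	0.640	hub, |kME + Cor|, GO
salmon	PPAN	C32677_c1_seq1_	Suppressor of SWI4 1 homolog	3.14	0.954	0.670	hub, |kME + Cor|, DEG, GO
salmon	G3BP1	C14804_c0_seq1_	Ras GTPase-activating protein-binding protein 1	1.72	0.946	0.601	hub, |kME + Cor|, GO
salmon	THUMPD1	C12905_c0_seq1_	THUMP domain-containing protein 1	2.45	0.940	0.558	hub, GO
salmon	WDR55	C88818_c0_seq1_	WD repeat-containing protein 55	2.29	0.939	0.564	hub, GO
salmon	FBL	C8062_c4_seq1_	rRNA 2'-O-methyltransferase fibrillarin	2.44	0.936	0.700	hub, |kME + Cor|, GO
salmon	NOP58	C11232_c0_seq1_	Nucleolar protein 58	1.81	0.927	0.657	hub, |kME + Cor|, GO
salmon	UTP3	C2534_c5_seq1_	Something about silencing protein 10	1.68	0.927	0.572	hub, GO
salmon	DDX27	C18812_c3_seq1_	Probable ATP-dependent RNA helicase DDX27	2.49	0.923	0.649	hub, |kME + Cor|, GO
salmon	PUM3	C34195_c0_seq1_	Pumilio homolog 3	1.66	0.919	0.551	hub, GO
salmon	PRG4	C97287_c0_seq1_	Proteoglycan 4	2.98	0.820	0.862	|kME + Cor|, DEG
salmon	UTP14A	C67976_c0_seq1_	U3 small nucleolar RNA-associated protein 14 homolog A	2.20	0.899	0.695	|kME + Cor|, GO
salmon	GSPT2	C3298_c64_seq1_	Eukaryotic peptide chain release factor GTP-binding subunit ERF3B	1.83	0.889	0.700	|kME + Cor|, GO
salmon	DDX56	C42805_c0_seq1_	Probable ATP-dependent RNA helicase DDX56	1.92	0.883	0.700	|kME + Cor|, GO
salmon	DDX5	C2190_c0_seq1_	Probable ATP-dependent RNA helicase DDX5	1.75	0.887	0.693	|kME + Cor|, GO
salmon	NOL8	C4288_c2_seq1_	Nucleolar protein 8	2.20	0.874	0.695	|kME + Cor|, GO
salmon	MPHOSPH10	C44411_c0_seq1_	U3 small nucleolar ribonucleoprotein protein MPP10	2.27	0.880	0.681	|kME + Cor|, GO
salmon	DNAJC21	C69765_c0_seq1_	DnaJ homolog subfamily C member 21	2.23	0.918	0.639	|kME + Cor|, GO
purple	EPCAM	C5086_c0_seq1_	Epithelial cell adhesion molecule	-1.64	0.907	-0.728	hub, |kME + Cor|
purple	LRRC8C	C63231_c0_seq1_	Volume-regulated anion channel subunit LRRC8C	-1.59	0.903	-0.713	hub, |kME + Cor|
purple	TXNIP	C5425_c0_seq1_	Thioredoxin-interacting protein	-3.22	0.883	-0.786	hub, |kME + Cor|, DEG
purple	KCNK5	C252072_c0_seq1_	Potassium channel subfamily K member 5	-2.04	0.871	-0.836	hub, |kME + Cor|
purple	G6PC	C1131_c10_seq1_	Glucose-6-phosphatase	-2.73	0.867	-0.576	hub
purple	slc25a36a	C38649_c0_seq1_	Solute carrier family 25 member 36-A	-2.77	0.861	-0.890	hub, |kME + Cor|, DEG
purple	IL17REL	C172972_c0_seq1_	Putative interleukin-17 receptor E-like	NA	0.853	-0.868	hub, |kME + Cor|
purple	FRK	C38093_c0_seq1_	Tyrosine-protein kinase FRK	-1.94	0.848	-0.819	hub, |kME + Cor|
purple	CLDN7	C8490_c0_seq1_	Claudin-7	-1.59	0.845	-0.708	hub, |kME + Cor|
purple	CTDSP2	C35474_c2_seq1_	C-terminal domain RNA pol II polypeptide A small phosphatase 2	NA	0.837	-0.456	hub
purple	SH2D3C	C38962_c1_seq1_	SH2 domain-containing protein 3C	-2.85	0.836	-0.740	hub, |kME + Cor|
purple	TRAF4	C72471_c1_seq1_	TNF receptor-associated factor 4	-1.81	0.833	-0.868	hub
purple	SGPP1	C21854_c1_seq1_	Sphingosine-1-phosphate phosphatase 1	-1.38	0.823	-0.705	hub, |kME + Cor|
purple	GMDS	C990_c3_seq1_	GDP-mannose 4,6 dehydratase	-1.95	0.813	-0.698	hub
purple	SNX9	C11879_c1_seq1_	Sorting nexin-9	-1.24	0.763	-0.815	|kME + Cor|
purple	NUPR1	C338_c259_seq1_	Nuclear protein 1	-2.35	0.802	-0.744	|kME + Cor|
purple	GCHFR	C8225_c0_seq1_	GTP cyclohydrolase 1 feedback regulatory protein	-1.27	0.803	-0.716	|kME + Cor|
purple	CDH17	C4892_c0_seq1_	Cadherin-17	-1.65	0.782	-0.730	|kME + Cor|
purple	PPP1R3B	C74190_c0_seq1_	Protein phosphatase 1 regulatory subunit 3B	-3.73	0.793	-0.714	DEG
turquoise	C8A	C4068_c0_seq1_	Complement component C8 alpha chain	-2.45	0.982	-0.720	hub, |kME + Cor|
turquoise	CD302	C9467_c0_seq1_	CD302 antigen	-2.13	0.981	-0.657	hub
turquoise	SPP2	C411_c37_seq1_	Secreted phosphoprotein 24	-2.73	0.979	-0.737	hub, |kME + Cor|
turquoise	EEF1G	C738_c2_seq1_	Elongation factor 1-gamma	-2.20	0.978	-0.677	hub
turquoise	HGD	C6448_c0_seq1_	Homogentisate 1,2-dioxygenase	-2.31	0.976	-0.725	hub, |kME + Cor|, GO
turquoise	SERPIND1	C1669_c0_seq1_	Heparin cofactor 2	-1.98	0.975	-0.674	hub
turquoise	SLC25A5	C241_c1_seq1_	ADP/ATP translocase 2	-2.22	0.975	-0.658	hub
turquoise	TMEM254	C6445_c0_seq1_	Transmembrane protein 254	-2.41	0.972	-0.697	hub
turquoise	MCFD2	C32034_c2_seq1_	Multiple coagulation factor deficiency protein 2	-2.57	0.972	-0.694	hub
turquoise	PC	C9567_c1_seq1_	Pyruvate carboxylase	-2.23	0.972	-0.696	hub, GO
turquoise	EIF5A2	C1423_c0_seq1_	Eukaryotic translation initiation factor 5A-2	-2.07	0.969	-0.662	hub
turquoise	PABPC1	C1010_c11_seq1_	Polyadenylate-binding protein 1	-2.19	0.969	-0.695	hub
turquoise	CLDN25	C18414_c0_seq1_	Putative claudin-25	-3.05	0.911	-0.835	|kME + Cor|
turquoise	MDH2	C1150_c0_seq1_	Malate dehydrogenase	-3.42	0.923	-0.816	|kME + Cor|, DEG, GO
turquoise	POR	C8317_c2_seq1_	NADPH—cytochrome P450 reductase	-3.06	0.936	-0.783	|kME + Cor|, GO
turquoise	HSD17B4	C19585_c0_seq1_	Peroxisomal multifunctional enzyme type 2	-2.31	0.958	-0.760	|kME + Cor|, GO
turquoise	FRIM	C160_c6_seq1_	Ferritin, middle subunit	-1.85	0.899	-0.815	|kME + Cor|, GO
turquoise	slc25a36a	C40704_c0_seq1_	Solute carrier family 25 member 36-A	-4.93	0.858	-0.855	|kME + Cor|, DEG
turquoise	ADAMTS13	C9888_c0_seq1_	Disintegrin and metalloproteinase with thrombospondin motifs 13	-2.03	0.872	-0.839	|kME + Cor|
turquoise	CP	C751_c0_seq1_	Ceruloplasmin	-2.28	0.965	-0.744	|kME + Cor|, GO
turquoise	ATP5F1	C1003_c0_seq1_	ATP synthase subunit beta	-2.89	0.928	-0.781	|kME + Cor|
turquoise	GLDC	C18716_c1_seq1_	Glycine dehydrogenase (decarboxylating)	-2.92	0.946	-0.762	|kME + Cor|, GO
turquoise	PROC	C4100_c0_seq1_	Vitamin K-dependent protein C	-2.26	0.958	-0.746	|kME + Cor|
turquoise	TSPAN1	C5350_c0_seq1_	Tetraspanin-1	-2.64	0.862	-0.841	|kME + Cor|
turquoise	bty	C93306_c0_seq1_	Protein similar to bloodthirsty / butyrophilin / TRIMs	-4.79	0.754	-0.874	DEG
turquoise	CES1	C37286_c0_seq1_	Liver carboxylesterase 1	-4.01	0.828	-0.778	DEG
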