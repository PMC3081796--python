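timepoint	protein_accession	gene_id	description	detect_c	detect_t	ratio	p_adjusted
4h	Q8SPT9	3875	Keratin 18 (CK18)	1	6	16.8935	0.000783
4h	Q3YAQ9	5230	Phosphoglycerate kinase 1 (PGK1)	5	6	5.0837	0.000309
4h	Q6XML5	721	Complement factor 4 (C4)	6	6	2.7795	0.019637
4h	Q8WNP0	2525	Lewis alpha-3-fucosyltransferase (FUT3)	6	6	2.2793	0.002356
4h	Q1HKZ4	1969	Ephrin receptor A2 (EPHA2)	6	6	2.2169	0.003633
4h	Q9TUC6	1138	Nicotinic receptor alpha 5 subunit (CHRNA5)	0	5	-	0.003949
4h	Q28864	7035	Tissue factor pathway inhibitor (TFPI)	0	4	-	0.029670
4h	B0JDR3	3106	MHC class I antigen (HLA-B)	0	3	-	0.001778
1d	Q3YAQ9	5230	Phosphoglycerate kinase 1 (PGK1)	2	6	24.6994	2.62E-13
1d	Q8SPT9	3875	Keratin 18 (CK18)	2	6	22.7121	5.42E-12
1d	Q8WNP0	2525	Lewis alpha-3-fucosyltransferase (FUT3)	5	6	15.3307	0.00E+00
1d	B1NL87	64816	Cytochrome P450, 3A43 (CYP3A43)	3	6	6.2458	0.013228
1d	A9XEK3	146	Alpha-1D adrenoceptor (ADRA1D)	4	5	6.0684	0.00E+00
1d	P47899	153	Beta-1 adrenergic receptor (ADRB1)	3	4	4.3532	0.000097
1d	Q5TM61	5514	Protein phosphatase 1, regulatory subunit 10 (PPP1R10)	5	6	4.3240	4.47E-07
1d	B3Y660	51311	Toll-like receptor 8 (TLR8)	6	6	3.2290	0.00E+00
1d	Q1HKZ4	1969	Ephrin receptor A2 (EPHA2)	6	6	2.7874	0.000157
1d	Q8HYQ1	6352	C-C motif chemokine 5 (CCL5)	0	6	-	0.000238
1d	Q3YAN2	51185	Cereblon (CRBN)	0	6	-	0.016533
1d	Q4G3V3	793	28kDa calbindin 1 (CALB1)	0	6	-	0.041927
3d	Q50KV9	54429	Taste receptor type 2 (TAS2R5)	3	5	5.6981	0.002844
3d	B0S4P2	148	Alpha-1A adrenoceptor (ADRA1A)	4	6	5.2097	0.011880
3d	Q9N143	7297	Tyrosine kinase-2 (TYK2)	6	6	2.2057	0.021489
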