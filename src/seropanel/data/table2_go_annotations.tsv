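protein_accession	gene_id	process_go_id	process_label	component_go_id	component_label
A9XEK3	146	GO:0007165	Signal transduction	GO:0016021	Integral to membrane
P47899	153	GO:0007165	Signal transduction	GO:0016021	Integral to membrane
Q1HKZ4	1969	GO:0007165	Signal transduction	GO:0016021	Integral to membrane
Q50KV9	54429	GO:0007165	Signal transduction	GO:0016021	Integral to membrane
Q9TUC6	1138	GO:0007165	Signal transduction	GO:0016021	Integral to membrane
B0S4P2	148	GO:0007165	Signal transduction	GO:0016021	Integral to membrane
B3Y660	51311	GO:0006955	Immune response	GO:0016021	Integral to membrane
B0JDR3	3106	GO:0006955	Immune response	GO:0016021	Integral to membrane
Q8WNP0	2525	GO:0043687	Post-translational protein modification	GO:0031090	Organelle membrane
B1NL87	64816	GO:0055114	Oxidation reduction	GO:0031090	Organelle membrane
Q3YAQ9	5230	GO:0043687	Post-translational protein modification	GO:0005737	Cytoplasm
Q3YAN2	51185	GO:0043687	Post-translational protein modification	GO:0005737	Cytoplasm
Q9N143	7297	GO:0043687	Post-translational protein modification	GO:0005737	Cytoplasm
Q8SPT9	3875	GO:0006915	Apoptosis	GO:0005737	Cytoplasm
Q4G3V3	793	GO:0048167	Regulation of synaptic plasticity	GO:0005737	Cytoplasm
Q5TM61	5514	GO:0006350	Transcription	GO:0005634	Nucleus
Q8HYQ1	6352	GO:0006954	Inflammatory response	GO:0005576	Extracellular region
Q6XML5	721	GO:0006954	Inflammatory response	GO:0005576	Extracellular region
Q28864	7035	GO:0007596	Blood coagulation	GO:0005576	Extracellular region
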