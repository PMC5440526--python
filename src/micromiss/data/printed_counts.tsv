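comparison	modality	level	k_case	n_case	k_control	n_control	test	printed_p
ut_all_species	culturomics	beta_diversity	151	335	185	281	chi2	2.5e-7
ut_anaerobic_species	culturomics	beta_diversity	43	111	76	112	chi2	0.00001
ut_aerotolerant_species	culturomics	beta_diversity	108	224	109	169	chi2	0.001
Actinobacteria	culturomics	phylum	47	335	42	281	chi2	0.74
Bacteroidetes	culturomics	phylum	21	335	21	281	chi2	0.55
Firmicutes	culturomics	phylum	208	335	192	281	chi2	0.1
Fusobacteria	culturomics	phylum	3	335	0	281	fisher	0.32
Proteobacteria	culturomics	phylum	56	335	25	281	chi2	0.004
Actinobacteria	metagenomics	phylum	86	589	61	486	chi2	0.37
Bacteroidetes	metagenomics	phylum	44	589	46	486	fisher	0.24
Chloroflexi	metagenomics	phylum	1	589	0	486	fisher	0.36
Euryarchaeota	metagenomics	phylum	0	589	4	486	fisher	0.027
Firmicutes	metagenomics	phylum	319	589	296	486	chi2	0.026
Fusobacteria	metagenomics	phylum	7	589	1	486	fisher	0.12
Lentisphaerae	metagenomics	phylum	0	589	1	486	fisher	0.90
Proteobacteria	metagenomics	phylum	131	589	75	486	chi2	0.004
Tenericutes	metagenomics	phylum	0	589	1	486	fisher	0.90
Verrucomicrobia	metagenomics	phylum	1	589	1	486	fisher	>0.99
Actinobacteria	metagenomics	class	69	589	38	486	chi2	0.033
Coriobacteriia	metagenomics	class	16	589	22	486	chi2	0.109
Bacteroidia	metagenomics	class	38	589	46	486	chi2	0.066
Flavobacteriia	metagenomics	class	0	589	4	486	fisher	0.082
Sphingobacteriia	metagenomics	class	2	589	0	486	fisher	0.59
Bacilli	metagenomics	class	158	589	124	486	chi2	0.63
Clostridia	metagenomics	class	115	589	132	486	chi2	0.003
Erysipelotrichia	metagenomics	class	11	589	14	486	chi2	0.27
Negativicutes	metagenomics	class	31	589	25	486	chi2	>0.99
Tissierellia	metagenomics	class	4	589	1	486	fisher	0.50
Alphaproteobacteria	metagenomics	class	22	589	2	486	chi2	0.0002
Betaproteobacteria	metagenomics	class	12	589	6	486	chi2	0.31
Deltaproteobacteria	metagenomics	class	5	589	3	486	chi2	0.94
Epsilonproteobacteria	metagenomics	class	2	589	2	486	fisher	>0.99
Gammaproteobacteria	metagenomics	class	91	589	63	486	chi2	0.25
Fusobacteriia	metagenomics	class	7	589	1	486	chi2	0.12
Lentisphaeria	metagenomics	class	0	589	1	486	fisher	0.90
Mollicutes	metagenomics	class	0	589	1	486	fisher	0.90
Verrucomicrobiae	metagenomics	class	1	589	1	486	fisher	>0.99
Chloroflexia	metagenomics	class	1	589	0	486	fisher	>0.99
Streptococcus	metagenomics	genus	40	589	23	486	chi2	0.029
Prevotella	metagenomics	genus	2	589	14	486	chi2	0.0006
Bacillus	metagenomics	genus	11	589	28	486	chi2	0.0006
Streptococcus gallolyticus	metagenomics	species_presence	7	10	0	5	barnard	0.014
Streptococcus peroris	metagenomics	species_presence	9	10	1	5	barnard	0.009
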