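label	modality	mean_case	sd_case	n_case	mean_control	sd_control	n_control	test	printed_p
new_species_per_sample	culturomics	1.8	1.5	10	5.0	2.6	5	t	0.009
not_known_human_species_per_sample	culturomics	1.5	1.2	10	2.8	0.4	5	mannwhitney	0.02
human_not_gut_species_per_sample	culturomics	1.2	0.8	10	1.4	0.9	5	mannwhitney	0.75
shannon_all	metagenomics	3.2	0.8	10	3.8	0.8	5	t	0.19
shannon_aerotolerant	metagenomics	2.07	0.8	10	1.35	0.6	5	t	0.1
shannon_anaerobic	metagenomics	1.05	0.98	10	3.1	1.5	5	mannwhitney	0.02
unassigned_read_fraction	metagenomics	0.05	0.02	10	0.26	0.22	5	t	0.009
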