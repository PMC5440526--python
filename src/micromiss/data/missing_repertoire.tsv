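species	obligate_anaerobe	phylum	class	order	family	genus	probiotic
Acinetobacter lwoffii	0	Proteobacteria	Gammaproteobacteria	Pseudomonadales	Moraxellaceae	Acinetobacter	no
Alistipes indistinctus	1	Bacteroidetes	Bacteroidia	Bacteroidales	Rikenellaceae	Alistipes	yes
Alistipes putredinis	1	Bacteroidetes	Bacteroidia	Bacteroidales	Rikenellaceae	Alistipes	no
Alistipes senegalensis	1	Bacteroidetes	Bacteroidia	Bacteroidales	Rikenellaceae	Alistipes	no
Alloscardovia omnicolens	0	Actinobacteria	Actinobacteria	Bifidobacteriales	Bifidobacteriaceae	Alloscardovia	no
Anaerostipes caccae	1	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Anaerostipes	yes
Arthrobacter agilis	0	Actinobacteria	Actinobacteria	Micrococcales	Micrococcaceae	Arthrobacter	no
Asaccharospora irregularis	1	Firmicutes	Clostridia	Clostridiales	Peptostreptococcaceae	Asaccharospora	no
Bacillus cereus	0	Firmicutes	Bacilli	Bacillales	Bacillaceae	Bacillus	no
Bacillus firmus	0	Firmicutes	Bacilli	Bacillales	Bacillaceae	Bacillus	no
Bacillus idriensis	0	Firmicutes	Bacilli	Bacillales	Bacillaceae	Bacillus	no
Bacillus licheniformis	0	Firmicutes	Bacilli	Bacillales	Bacillaceae	Bacillus	yes
Bacillus niabensis	0	Firmicutes	Bacilli	Bacillales	Bacillaceae	Bacillus	no
Bacillus subtilis	0	Firmicutes	Bacilli	Bacillales	Bacillaceae	Bacillus	yes
Bacillus thermoamylovorans	0	Firmicutes	Bacilli	Bacillales	Bacillaceae	Bacillus	no
Bacteroides salyersiae	1	Bacteroidetes	Bacteroidia	Bacteroidales	Bacteroidaceae	Bacteroides	yes
Bifidobacterium adolescentis	1	Actinobacteria	Actinobacteria	Bifidobacteriales	Bifidobacteriaceae	Bifidobacterium	yes
Clostridium amygdalinum	1	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Lachnoclostridium	no
Clostridium cadaveris	1	Firmicutes	Clostridia	Clostridiales	Clostridiaceae	Clostridium	no
Clostridium glycolicum	1	Firmicutes	Clostridia	Clostridiales	Peptostreptococcaceae	Terrisporobacter	yes
Clostridium hylemonae	1	Firmicutes	Clostridia	Clostridiales	Clostridiaceae	Clostridium	no
Clostridium neonatale	1	Firmicutes	Clostridia	Clostridiales	Clostridiaceae	Clostridium	no
Clostridium oroticum	1	Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Lachnoclostridium	no
Clostridium paraputrificum	1	Firmicutes	Clostridia	Clostridiales	Clostridiaceae	Clostridium	no
Clostridium saccharolyticum	1	Firmicutes	Clostridia	Clostridiales	Clostridiaceae	Clostridium	no
Clostridium sordellii	1	Firmicutes	Clostridia	Clostridiales	Peptostreptococcaceae	Peptoclostridium	no
Dialister pneumosintes	1	Firmicutes	Negativicutes	Selenomonadales	Veillonellaceae	Dialister	no
Enterococcus dispar	0	Firmicutes	Bacilli	Lactobacillales	Enterococcaceae	Enterococcus	no
Faecalitalea cylindroides	1	Firmicutes	Erysipelotrichia	Erysipelotrichales	Erysipelotrichaceae	Faecalitalea	no
Gemella sanguinis	0	Firmicutes	Bacilli	Bacillales	Bacillales Family XI Incertae Sedis	Gemella	no
Intestinimonas butyriciproducens	1	Firmicutes	Clostridia	Clostridiales	Unclassified clostridiales	Intestinimonas	yes
Lactobacillus parabuchneri	0	Firmicutes	Bacilli	Lactobacillales	Lactobacillaceae	Lactobacillus	yes
Lactobacillus perolens	0	Firmicutes	Bacilli	Lactobacillales	Lactobacillaceae	Lactobacillus	yes
Lactobacillus vaccinostercus	0	Firmicutes	Bacilli	Lactobacillales	Lactobacillaceae	Lactobacillus	yes
Micrococcus lylae	0	Actinobacteria	Actinobacteria	Micrococcales	Micrococcaceae	Micrococcus	no
Neisseria flavescens	0	Proteobacteria	Betaproteobacteria	Neisseriales	Neisseriaceae	Neisseria	no
Pantoea septica	0	Proteobacteria	Gammaproteobacteria	Enterobacteriales	Enterobacteriaceae	Pantoea	no
Paraclostridium bifermentans	1	Firmicutes	Clostridia	Clostridiales	Peptostreptococcaceae	Paraclostridium	no
Slackia exigua	1	Actinobacteria	Coriobacteriia	Eggerthellales	Eggerthellaceae	Slackia	no
Staphylococcus haemolyticus	0	Firmicutes	Bacilli	Bacillales	Staphylococcaceae	Staphylococcus	no
Staphylococcus hominis	0	Firmicutes	Bacilli	Bacillales	Staphylococcaceae	Staphylococcus	no
Streptococcus vestibularis	0	Firmicutes	Bacilli	Lactobacillales	Streptococcaceae	Streptococcus	no
Sutterella wadsworthensis	1	Proteobacteria	Betaproteobacteria	Burkholderiales	Sutterellaceae	Sutterella	no
Veillonella dispar	1	Firmicutes	Negativicutes	Selenomonadales	Veillonellaceae	Veillonella	no
Weissella confusa	0	Firmicutes	Bacilli	Lactobacillales	Leuconostocaceae	Weissella	yes
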