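species	obligate_anaerobe	phylum	function
Alistipes indistinctus	1	Bacteroidetes	Common member of the gut microbiota of healthy humans
Anaerostipes caccae	1	Firmicutes	Common member of the gut microbiota of healthy humans
Bacillus licheniformis	0	Firmicutes	Antibacterial potential
Bacillus subtilis	0	Firmicutes	Antibacterial potential
Bacteroides salyersiae	1	Bacteroidetes	Mutualistic association with Terrisporobacter glycolicus for polysaccharide fermentation
Bifidobacterium adolescentis	1	Actinobacteria	Common member of the gut microbiota in healthy breastfed infants
Intestinimonas butyriciproducens	1	Firmicutes	Butyrate production
Lactobacillus parabuchneri	0	Firmicutes	Common member of the gut microbiota of healthy breastfed infants
Lactobacillus perolens	0	Firmicutes	Common member of the gut microbiota of healthy breastfed infants
Lactobacillus vaccinostercus	0	Firmicutes	Common member of the gut microbiota of healthy breastfed infants
Terrisporobacter glycolicus	1	Firmicutes	Mutualistic association with acetogenic Bacteroides for polysaccharide fermentation
Weissella confusa	0	Firmicutes	Antioxidant metabolism
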