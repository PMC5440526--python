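species	family	oxygen_tolerant	origin	novelty
Africanella massiliensis	Ruminococcaceae	no	control	new_genus
Bacillus massilionigeriensis	Bacillaceae	yes	control	new_species
Bacillus mediterraneensis	Bacillaceae	yes	control	new_species
Bacillus phoceensis	Bacillaceae	yes	control	new_species
Bacillus testis	Bacillaceae	yes	control	new_species
Bacillus touaregensis	Bacillaceae	yes	control	new_species
Brachybacterium massiliense	Dermabacteraceae	yes	control	new_species
Brevibacterium phoceense	Brevibacteriaceae	yes	control	new_species
Clostridium massiliodielmoense	Clostridiaceae	no	control	new_species
Clostridium nigeriense	Clostridiaceae	no	control	new_species
Enterobacter timonensis	Enterobacteriaceae	yes	control	new_species
Khelaifiabacterium massiliensis	Clostridiaceae	no	control	new_genus
Lachnoclostridium massiliosenegalense	Lachnospiraceae	no	control	new_species
Lachnoclostridium touaregense	Lachnospiraceae	no	control	new_species
Lagierella massiliensis	Peptoniphilaceae	no	control	new_genus
Lascolabacillus massiliensis	Porphyromonadaceae	no	control	new_genus
Massiliobacillus massiliensis	Sporomusaceae	no	control	new_genus
Murdochiella massiliensis	Peptoniphilaceae	no	control	new_species
Ndiopella massiliensis	Peptoniphilaceae	no	control	new_genus
Neofamilia massiliensis	Neofamiliaceae	no	control	new_family
Niameyia massiliensis	Lachnospiraceae	no	control	new_genus
Paenibacillus phoceensis	Paenibacillaceae	yes	control	new_species
Paenibacillus senegalomassiliensis	Paenibacillaceae	yes	control	new_species
Paenibacillus touaregensis	Paenibacillaceae	yes	control	new_species
Peptoniphilus phoceensis	Peptoniphilaceae	no	control	new_species
Senegalia massiliensis	Clostridiaceae	no	control	new_genus
Anaerococcus rubiinfantis	Peptoniphilaceae	no	case	new_species
Anaeromassilibacillus senegalensis	Ruminococcaceae	no	case	new_genus
Anaerotruncus rubiinfantis	Ruminococcaceae	no	case	new_species
Bacillus andreraoultii	Bacillaceae	yes	case	new_species
Bacillus niameyensis	Bacillaceae	yes	case	new_species
Bacillus rubiinfantis	Bacillaceae	yes	case	new_species
Desnuesiella massiliensis	Clostridiaceae	yes	case	new_genus
Flaviflexus massiliensis	Actinomycetaceae	yes	case	new_species
Inediibacterium massiliense	Clostridiaceae	no	case	new_genus
Massilibacterium senegalense	Bacillaceae	yes	case	new_genus
Mediannikovella massiliensis	Clostridiaceae	no	case	new_genus
Mobilicoccus massiliensis	Dermatophilaceae	yes	case	new_species
Nigerium massiliensis	Propionibacteriaceae	no	case	new_genus
Olsenella massiliensis	Atopobiaceae	no	case	new_species
Paenibacillus rubiinfantis	Paenibacillaceae	yes	case	new_species
Rubeoparvulum massiliense	Bacillaceae	no	case	new_genus
Rubiinfantum massiliense	Bacillaceae	yes	case	new_genus
Tessaracoccus massiliensis	Propionibacteriaceae	yes	case	new_species
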