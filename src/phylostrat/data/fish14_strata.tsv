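taxon	stratum	stratum_name
Bacteria	1	Cellular_organisms
Archaea	1	Cellular_organisms
Viridiplantae	2	Eukaryota
Alveolata	2	Eukaryota
Amoebozoa	2	Eukaryota
Euglenozoa	2	Eukaryota
Fungi	3	Opisthokonta
Choanoflagellata	4	Holozoa
Filasterea	4	Holozoa
Porifera	5	Metazoa
Cnidaria	6	Eumetazoa
Ctenophora	6	Eumetazoa
Placozoa	6	Eumetazoa
Arthropoda	7	Bilateria
Nematoda	7	Bilateria
Mollusca	7	Bilateria
Annelida	7	Bilateria
Echinodermata	8	Chordata
Hemichordata	8	Chordata
Cephalochordata	8	Chordata
Tunicata	9	Olfactores
Cyclostomata	10	Vertebrata
Chondrichthyes	11	Gnathostomata
Coelacanthimorpha	12	Euteleostomi
Amphibia	12	Euteleostomi
Sauropsida	12	Euteleostomi
Mammalia	12	Euteleostomi
Percomorpha	13	Clupeocephala
Salmoniformes	13	Clupeocephala
Gadiformes	13	Clupeocephala
Characiformes	14	Otophysa
Danio_rerio	14	Otophysa
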