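((Bacteria,Archaea),((Viridiplantae,Alveolata,Amoebozoa,Euglenozoa),(Fungi,((Choanoflagellata,Filasterea),(Porifera,((Cnidaria,Ctenophora,Placozoa),((Arthropoda,Nematoda,Mollusca,Annelida),((Echinodermata,Hemichordata,Cephalochordata),(Tunicata,(Cyclostomata,(Chondrichthyes,((Actinopterygii,Coelacanthimorpha),(Amphibia,(Sauropsida,(Monotremata,(Marsupialia,((Afrotheria,Xenarthra,Laurasiatheria),((Primates,Dermoptera,Scandentia),((Lagomorpha,Sciuridae),(Rattus,Mus_musculus))))))))))))))))))));
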