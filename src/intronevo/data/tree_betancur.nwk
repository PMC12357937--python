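(Cartilaginous,((Lobe_finned,Tetrapod)Sarcopterygii,(Basal_rayfinned,(Basal_teleost,((EsoSalArg,Galaxiiformes)Protacanthopterygii,OsmStom,(Eurypterygii_core,Syngnathid_clade,Notothenioid_crown)Eurypterygii)Euteleostei)Teleostei)Actinopterygii)Osteichthyes)Gnathostomata;
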