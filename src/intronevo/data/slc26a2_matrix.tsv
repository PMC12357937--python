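taxon	A1p	R1	Q1	O2	N1	N2
Cartilaginous	1	0	0	0	0	0
Lobe_finned	1	0	0	0	0	0
Tetrapod	1	0	0	0	0	0
Basal_rayfinned	1	1	0	0	0	0
Basal_teleost	1	1	0	0	0	0
EsoSalArg	1	1	0	0	0	0
OsmStom	1	1	0	1	0	0
Galaxiiformes	1	1	1	0	0	0
Eurypterygii_core	1	1	1	0	0	0
Syngnathid_clade	0	1	1	0	0	0
Notothenioid_crown	1	1	1	0	1	1
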