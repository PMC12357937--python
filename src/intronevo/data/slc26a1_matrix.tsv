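taxon	A1	E1	E2	E3	E4	E5	O1
Cartilaginous	1	0	0	0	0	0	0
Lobe_finned	1	0	0	0	0	0	0
Tetrapod	1	0	0	0	0	0	0
Basal_rayfinned	1	0	0	0	0	0	0
Basal_teleost	1	0	0	0	0	0	0
EsoSalArg	1	0	0	0	0	0	0
OsmStom	1	0	0	0	0	0	1
Galaxiiformes	1	1	0	0	1	0	0
Eurypterygii_core	1	1	1	1	1	1	0
Syngnathid_clade	1	1	1	1	1	1	0
Notothenioid_crown	1	1	1	1	1	1	0
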