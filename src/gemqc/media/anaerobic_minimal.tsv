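# Strict anaerobic minimal medium: as glucose minimal but no oxygen uptake.
reaction_id	lower_bound	upper_bound
r_1714	-10	inf
r_1654	-inf	inf
r_1992	0	inf
r_2005	-inf	inf
r_2060	-inf	inf
r_2100	-inf	inf
r_1832	-inf	inf
r_1861	-inf	inf
r_2020	-inf	inf
r_2049	-inf	inf
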