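# Anaerobic minimal medium supplemented with the six sterols (uptake -1).
# Sterol exchange ids are best-effort for the consensus yeast scheme:
# episterol, ergosterol, fecosterol, lanosterol, zymosterol and
# ergosta-5,7,22,24(28)-tetraen-3beta-ol. Override if your file differs.
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
r_1753	-1	inf
r_1757	-1	inf
r_1788	-1	inf
r_1915	-1	inf
r_2106	-1	inf
r_1761	-1	inf
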