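# panel: ZRC-Phuket
# notes: 20 formalin-fixed specimens from 4 Phuket lots housed in ZRC (ZRC 43693,
# ZRC 45718, ZRC 49182, ZRC 60821). All 20 have 8 pectoral-fin rays; 8 specimens
# have 7 + 7 or 7 + 8 branched caudal-fin rays and 12 have 8 + 8. The published
# account does not split the 8 between 7 + 7 and 7 + 8; this panel uses 4 + 4
# (both values fall inside the S. robertsi ranges, so every printed tally is
# unaffected by the split).
specimen	pectoral_rays	caudal_rays
ZRC-Phuket-01	8	/7 + 7/
ZRC-Phuket-02	8	/7 + 7/
ZRC-Phuket-03	8	/7 + 7/
ZRC-Phuket-04	8	/7 + 7/
ZRC-Phuket-05	8	/7 + 8/
ZRC-Phuket-06	8	/7 + 8/
ZRC-Phuket-07	8	/7 + 8/
ZRC-Phuket-08	8	/7 + 8/
ZRC-Phuket-09	8	/8 + 8/
ZRC-Phuket-10	8	/8 + 8/
ZRC-Phuket-11	8	/8 + 8/
ZRC-Phuket-12	8	/8 + 8/
ZRC-Phuket-13	8	/8 + 8/
ZRC-Phuket-14	8	/8 + 8/
ZRC-Phuket-15	8	/8 + 8/
ZRC-Phuket-16	8	/8 + 8/
ZRC-Phuket-17	8	/8 + 8/
ZRC-Phuket-18	8	/8 + 8/
ZRC-Phuket-19	8	/8 + 8/
ZRC-Phuket-20	8	/8 + 8/
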