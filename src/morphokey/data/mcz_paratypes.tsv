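# panel: MCZ-paratypes
# notes: 8 paratypes of S. robertsi from Phuket (MCZ 49164) examined in 1988;
# 4 have 7 + 8 branched caudal-fin rays and 4 have 8 + 8. Only the caudal
# formula is on record for these specimens.
specimen	caudal_rays
MCZ-49164-1	/7 + 8/
MCZ-49164-2	/7 + 8/
MCZ-49164-3	/7 + 8/
MCZ-49164-4	/7 + 8/
MCZ-49164-5	/8 + 8/
MCZ-49164-6	/8 + 8/
MCZ-49164-7	/8 + 8/
MCZ-49164-8	/8 + 8/
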