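# panel: robertsi-holotype
# notes: The re-examined holotype of S. robertsi has 7 + 7 branched caudal-fin
# rays and 8 and 7 pectoral-fin rays (right and left); the asymmetric pectoral
# count is stored as the observation set {7,8}.
specimen	caudal_rays	pectoral_rays
robertsi-holotype	/7 + 7/	{7,8}
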