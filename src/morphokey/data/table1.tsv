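# Canonical comparison matrix for the Schistura cincticauda species group
# (12 species x 18 characters). Transcribed from the published revision of the
# group; qualitative cells are normalised to closed-vocabulary tokens via the
# synonym map in table1_characters.json. "Variable" cells are stored as the
# polymorphic set present/absent; "?" marks data that could not be observed.
# The body_bars character carries the flank bar-pattern states defined in the
# revision's morphocode legend; its per-species values come from the species
# diagnoses and colour-pattern accounts (see table1_characters.json notes).
taxon	pectoral_rays	pelvic_rays	caudal_rays	lateral_line_pores	supraorbital_pores	infraorbital_pores	supratemporal_pores	preoperculomandibular_pores	lip_dots	caudal_bar	dorsal_dot	dorsal_stripes	anus_position	lateral_line_length	axillary_lobe	lip_dots_second	throat_blotch	body_bars
S. aurantiaca	9	7	/9 + 8/	6-26	7	/4 + 9/	3	9	present	light_thin	present	absent	middistance	intermediate	absent	absent	absent	numerous_broad
S. balteata	10-11	7	/8 + 8/	24-50	6	/4 + 11/	3	9	present/absent	absent	absent	present	middistance	long	present	absent	absent	few_thin
S. cincticauda	9	6-7	/9 + 8/	15-25	5	/4 + 10/	3	9	present/absent	dark_thick	present	absent	closer_pelvic	intermediate	absent	absent	absent	numerous_broad
S. crocotula	9	7	/8 + 8/	10-18	6	/4 + 9/	3	9	present	dark_thick	present	absent	closer_anal	short	absent	present	absent	numerous_broad
S. hartli	9	7	/8 + 8/	23-24	6	/4 + 9/	3	8	present	dark_thick	present	absent	middistance	intermediate	absent	absent	present	numerous_broad
S. ataranensis	9	7	/8 + 8/	18-31	6	/4 + 9/	3	9	present	dark_thick	absent	present	closer_pelvic	intermediate	present	absent	absent	mostly_fused
S. myaekanbawensis	8	7	/8 + 7/	12-18	6	/4 + 8-9/	3	9	present	dark_thick	present	absent	closer_pelvic	short	absent	present	absent	numerous_broad
S. kuehnei	9	7	/9 + 8/	14-22	6	/4 + 9/	3	9	present	incomplete	present	absent	middistance	intermediate	absent	absent	absent	numerous_broad
S. robertsi	7-8	7	/6-7 + 6-8/	7-12	6	/4 + 8/	4	9	present	dark_thick	present	absent	closer_anal	short	absent	absent	absent	numerous_broad
S. paucifasciata	10-11	7	/9 + 8?/	?	6	/4 + 11/	3	9	?	dark_thick	?	absent	closer_anal	intermediate	present	?	?	few_thin
S. peninsulae	9-10	7	/8-9 + 7-8/	9-15	5	/4 + 10/	3	9	present	dark_thick	present	absent	closer_anal	short	absent	absent	absent	numerous_broad
S. tenebrosa	9-10	7	/9 + 7-8/	18-30	6-8	/4 + 8-11/	3	7-10	present	dark_thick	present	absent	middistance	intermediate	present	absent	absent	plain_brown
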