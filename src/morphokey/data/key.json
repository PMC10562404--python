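{
  "provenance": "Dichotomous key to the species of the Schistura cincticauda species group, encoded from the printed key of the published revision. Live-colour and geography phrases are kept as soft predicates (excluded from routing by default); colour-pattern and lateral-line-reach phrases that correspond to matrix characters are encoded as hard predicates on those characters.",
  "start": 1,
  "couplets": [
    {"id": 1, "leads": [
      {"predicates": [
        {"char": "axillary_lobe", "in": ["present"], "text": "Axillary pelvic lobe present"}],
       "target": {"couplet": 2}},
      {"predicates": [
        {"char": "axillary_lobe", "in": ["absent"], "text": "No axillary pelvic lobe"}],
       "target": {"couplet": 5}}]},
    {"id": 2, "leads": [
      {"predicates": [
        {"char": "body_bars", "in": ["few_thin"],
         "text": "Colour pattern consisting of 2-4 thin dark bars below dorsal fin"}],
       "target": {"couplet": 3}},
      {"predicates": [
        {"char": "body_bars", "in": ["numerous_broad", "plain_brown", "mostly_fused"],
         "text": "Other colour pattern"}],
       "target": {"couplet": 4}}]},
    {"id": 3, "leads": [
      {"predicates": [
        {"char": "caudal_bar", "in": ["absent"], "text": "No black bar at base of caudal fin"},
        {"soft": true, "text": "3-5 black saddles on back"},
        {"char": "caudal_rays", "formula": [8, 8], "text": "8 + 8 branched caudal-fin rays"}],
       "target": {"taxon": "S. balteata"}},
      {"predicates": [
        {"char": "caudal_bar", "in": ["dark_thick", "light_thin", "incomplete"],
         "text": "A black bar at base of caudal fin"},
        {"soft": true, "text": "no dorsal saddles"},
        {"char": "caudal_rays", "formula": [9, 8], "text": "9 + 8 branched caudal-fin rays"}],
       "target": {"taxon": "S. paucifasciata"}}]},
    {"id": 4, "leads": [
      {"predicates": [
        {"char": "dorsal_stripes", "in": ["present"], "text": "Dorsal fin with 2-3 black stripes"},
        {"char": "caudal_rays", "formula": [8, 8], "text": "8 + 8 branched caudal-fin rays"},
        {"char": "dorsal_dot", "in": ["absent"],
         "text": "no black mark on anterior part of dorsal-fin base"}],
       "target": {"taxon": "S. ataranensis"}},
      {"predicates": [
        {"char": "dorsal_stripes", "in": ["absent"],
         "text": "Dorsal fin with a single row of spots or plain"},
        {"char": "caudal_rays", "formula": [9, 8], "text": "9 + 8 branched caudal-fin rays"},
        {"char": "dorsal_dot", "in": ["present"],
         "text": "a prominent black mark on anterior part of dorsal-fin base"}],
       "target": {"taxon": "S. tenebrosa"}}]},
    {"id": 5, "leads": [
      {"predicates": [
        {"char": "anus_position", "in": ["closer_pelvic"],
         "text": "Anus closer to pelvic-fin base than to anal-fin origin"}],
       "target": {"couplet": 6}},
      {"predicates": [
        {"char": "anus_position", "in": ["closer_anal", "middistance"],
         "text": "Anus closer to anal-fin origin than to pelvic-fin base, or at equal distance"}],
       "target": {"couplet": 7}}]},
    {"id": 6, "leads": [
      {"predicates": [
        {"char": "pectoral_rays", "range": [8, 8], "text": "8 pectoral-fin rays"},
        {"char": "caudal_rays", "formula": [8, 7], "text": "8 + 7 branched caudal-fin rays"},
        {"char": "lip_dots_second", "in": ["present"],
         "text": "a second pair of black dots on lower lip close to corners of mouth"}],
       "target": {"taxon": "S. myaekanbawensis"}},
      {"predicates": [
        {"char": "pectoral_rays", "range": [9, 11], "text": "9-11 pectoral-fin rays"},
        {"char": "caudal_rays", "formula": [9, 8], "text": "9 + 8 branched caudal-fin rays"},
        {"char": "lip_dots_second", "in": ["absent"],
         "text": "a single pair of black dots on lower lip"}],
       "target": {"taxon": "S. cincticauda"}}]},
    {"id": 7, "leads": [
      {"predicates": [
        {"char": "anus_position", "in": ["middistance"],
         "text": "Anus at equal distance between pelvic-fin base and anal-fin origin"}],
       "target": {"couplet": 8}},
      {"predicates": [
        {"char": "anus_position", "in": ["closer_anal"],
         "text": "Anus closer to anal-fin origin than to pelvic-fin base"}],
       "target": {"couplet": 9}}]},
    {"id": 8, "leads": [
      {"predicates": [
        {"char": "caudal_rays", "formula": [8, 8], "text": "8 + 8 branched caudal-fin rays"},
        {"char": "caudal_bar", "in": ["dark_thick"],
         "text": "black bar at caudal-fin base regular (without interruption)"},
        {"char": "throat_blotch", "in": ["present"],
         "text": "a black patch on throat, posteriorly of median interruption of lower lip"}],
       "target": {"taxon": "S. hartli"}},
      {"predicates": [
        {"char": "caudal_rays", "formula": [9, 8], "text": "9 + 8 branched caudal-fin rays"},
        {"char": "caudal_bar", "in": ["incomplete"],
         "text": "black bar at base of caudal fin irregular (with interruption)"},
        {"char": "throat_blotch", "in": ["absent"], "text": "no black patch on throat"}],
       "target": {"taxon": "S. kuehnei"}}]},
    {"id": 9, "leads": [
      {"predicates": [
        {"char": "caudal_rays", "lobe": "upper", "range": [6, 7],
         "text": "6-7 branched rays in upper caudal-fin lobe"},
        {"char": "pectoral_rays", "range": [7, 8], "text": "7-8 rays in pectoral fin"}],
       "target": {"taxon": "S. robertsi"}},
      {"predicates": [
        {"char": "caudal_rays", "lobe": "upper", "range": [8, 9],
         "text": "8-9 branched rays in upper caudal-fin lobe"},
        {"char": "pectoral_rays", "range": [9, 11], "text": "9-11 rays in pectoral fin"}],
       "target": {"couplet": 10}}]},
    {"id": 10, "leads": [
      {"predicates": [
        {"soft": true,
         "text": "Brown bars with yellowish interspaces in live specimens; all interspaces very narrow (at most 1/3 of width of bars) and all of similar width"}],
       "target": {"taxon": "S. peninsulae"}},
      {"predicates": [
        {"soft": true,
         "text": "Brown bars with orange to red interspaces on live specimens; interspaces wider than 1/2 of width of bars; interspaces under dorsal fin wider"}],
       "target": {"couplet": 11}}]},
    {"id": 11, "leads": [
      {"predicates": [
        {"char": "caudal_rays", "formula": [8, 8], "text": "8 + 8 branched caudal-fin rays"},
        {"char": "lateral_line_length", "in": ["short"],
         "text": "lateral line reaching at most halfway between pectoral-fin base and dorsal-fin origin"},
        {"soft": true, "text": "coastal streams in Prachuap Khiri Khan Province, southern Thailand"}],
       "target": {"taxon": "S. crocotula"}},
      {"predicates": [
        {"char": "caudal_rays", "formula": [9, 8], "text": "9 + 8 branched caudal-fin rays"},
        {"char": "lateral_line_length", "in": ["intermediate"],
         "text": "lateral line reaching vertical through dorsal-fin origin"},
        {"soft": true, "text": "head waters of Mae Klong, Ataran and Moei rivers"}],
       "target": {"taxon": "S. aurantiaca"}}]}
  ]
}
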