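{
  "provenance": "Morphocode character/state scheme of the published revision of the Schistura cincticauda species group: twelve integer-coded characters A-L mapped onto the canonical comparison matrix.",
  "characters": [
    {"code": "A", "label": "number of pectoral-fin rays", "source": "pectoral_rays",
     "legend": "0 = 9, 1 = 10-11, 2 = 8",
     "states": {"0": {"counts": [9]}, "1": {"counts": [10, 11]}, "2": {"counts": [8]}}},
    {"code": "B", "label": "number of branched caudal-fin rays", "source": "caudal_rays",
     "legend": "0 = 9 + 8, 1 = 8 + 8, 2 = 7 + 8, 3 = 8 + 7",
     "states": {"0": {"formula": [9, 8]}, "1": {"formula": [8, 8]},
                "2": {"formula": [7, 8]}, "3": {"formula": [8, 7]}}},
    {"code": "C", "label": "length of lateral line", "source": "lateral_line_length",
     "legend": "0 = long [ending behind dorsal fin base], 1 = intermediate, 2 = short [ending before middistance from pectoral to pelvic-fin base]",
     "states": {"0": {"tokens": ["long"]}, "1": {"tokens": ["intermediate"]},
                "2": {"tokens": ["short"]}}},
    {"code": "D", "label": "position of anus", "source": "anus_position",
     "legend": "0 = half distance between pelvic to anal fin, 1 = closer to pelvic fin, 2 = closer to anal fin",
     "states": {"0": {"tokens": ["middistance"]}, "1": {"tokens": ["closer_pelvic"]},
                "2": {"tokens": ["closer_anal"]}}},
    {"code": "E", "label": "black dots on lower lip", "source": "lip_dots",
     "legend": "0 = present, 1 = variable",
     "states": {"0": {"tokens": ["present"]}, "1": {"tokens": ["present", "absent"]}}},
    {"code": "F", "label": "axillary pelvic lobe", "source": "axillary_lobe",
     "legend": "0 = absent, 1 = present",
     "states": {"0": {"tokens": ["absent"]}, "1": {"tokens": ["present"]}}},
    {"code": "G", "label": "black bar on base of caudal fin", "source": "caudal_bar",
     "legend": "0 = present, 1 = absent, 2 = irregular",
     "states": {"0": {"tokens": ["dark_thick", "light_thin"]}, "1": {"tokens": ["absent"]},
                "2": {"tokens": ["incomplete"]}}},
    {"code": "H", "label": "black blotch posterior of median incision of lower lip", "source": "throat_blotch",
     "legend": "0 = absent, 1 = present",
     "states": {"0": {"tokens": ["absent"]}, "1": {"tokens": ["present"]}}},
    {"code": "I", "label": "second pair of black dots on lower lip", "source": "lip_dots_second",
     "legend": "0 = absent, 1 = present",
     "states": {"0": {"tokens": ["absent"]}, "1": {"tokens": ["present"]}}},
    {"code": "J", "label": "black dot on base of dorsal fin", "source": "dorsal_dot",
     "legend": "0 = present, 1 = absent",
     "states": {"0": {"tokens": ["present"]}, "1": {"tokens": ["absent"]}}},
    {"code": "K", "label": "black bars on dorsal fin", "source": "dorsal_stripes",
     "legend": "0 = absent, 1 = present",
     "states": {"0": {"tokens": ["absent"]}, "1": {"tokens": ["present"]}}},
    {"code": "L", "label": "bars of body", "source": "body_bars",
     "legend": "0 = bars numerous, broad or grey, 1 = 2 to 4 very thin black contrasting bars in middle of flank, 2 = all bars fused into plain brown body, 3 = most bars fused leaving few interspaces in middle of flank",
     "states": {"0": {"tokens": ["numerous_broad"]}, "1": {"tokens": ["few_thin"]},
                "2": {"tokens": ["plain_brown"]}, "3": {"tokens": ["mostly_fused"]}}}
  ],
  "notes": [
    "The light, thin caudal bar of S. aurantiaca is coded as state 0 (bar present) of character G; the legend does not define a separate state for it.",
    "Per-species code strings are derived from the matrix through these mappings (see derive_morphocode); values outside a legend are resolved by the documented range-overlap rule and flagged with a warning."
  ]
}
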