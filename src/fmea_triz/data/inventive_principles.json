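{
 "1": "Segmentation",
 "2": "Taking Out",
 "3": "Local Quality",
 "4": "Asymmetry",
 "5": "Merging",
 "6": "Universality",
 "7": "Nested Doll",
 "8": "Anti-Weight",
 "9": "Preliminary Anti-Action",
 "10": "Preliminary Action",
 "11": "Beforehand Cushioning",
 "12": "Equipotentiality",
 "13": "The Other Way Round",
 "14": "Spheroidality",
 "15": "Dynamics",
 "16": "Partial or Excessive Actions",
 "17": "Another Dimension",
 "18": "Mechanical Vibration",
 "19": "Periodic Action",
 "20": "Continuity of Useful Action",
 "21": "Rushing Through",
 "22": "Blessing in Disguise",
 "23": "Feedback",
 "24": "Intermediary",
 "25": "Self-Service",
 "26": "Copying",
 "27": "Cheap Short-Living Objects",
 "28": "Replacement of Mechanical Systems",
 "29": "Pneumatics and Hydraulics",
 "30": "Flexible Shells and Thin Films",
 "31": "Porous Materials",
 "32": "Color Changes",
 "33": "Homogeneity",
 "34": "Discarding and Recovering",
 "35": "Parameter Changes",
 "36": "Phase Transitions",
 "37": "Thermal Expansion",
 "38": "Strong Oxidants",
 "39": "Inert Atmosphere",
 "40": "Composite Materials"
}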