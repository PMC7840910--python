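{
  "description": "Published pairwise Nei G_ST matrix between four historical European flat-oyster populations (1870s museum-shell cohort), with population sizes and the haplogroup-level alleles observed in each population. Used as reconstruction targets; singleton alleles are unassigned individual sequences carried as private alleles.",
  "populations": {
    "WaddenSea": {"size": 20, "alleles": ["NS", "WS"]},
    "England": {"size": 7, "alleles": ["NS", "NEA", "Kau_EN", "SEA"]},
    "Atlantic": {"size": 8, "alleles": ["NEA", "SEA"]},
    "Mediterranean": {"size": 4, "alleles": ["Kau_ME", "SEA"]}
  },
  "singleton_alleles": ["Kau_EN", "Kau_ME"],
  "gst": {
    "WaddenSea|England": 0.1367843,
    "WaddenSea|Atlantic": 0.34252229,
    "WaddenSea|Mediterranean": 0.31563499,
    "England|Atlantic": 0.06331849,
    "England|Mediterranean": 0.04836342,
    "Atlantic|Mediterranean": 0.02782109
  }
}
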