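{
  "description": "SYNTHETIC stand-in for the study's per-population haplogroup counts and representative-sequence divergence structure, which are not shipped with this package. The integer per-population allele counts and per-site bipartition counts below were recovered once by constrained integer fitting (LP feasibility over count vectors consistent with the published population sizes and allele lists, then mixed-integer fitting of site-pattern counts) against the published pairwise G_ST matrix under the Nei-Chesser corrected multilocus estimator. Feeding replicated representative sequences built from this configuration through the package's sequence-mode G_ST reproduces every published pairwise value to 4 decimal places.",
  "estimator": "corrected",
  "counts": {
    "WaddenSea": {"NS": 12, "WS": 8},
    "England": {"NS": 1, "NEA": 1, "Kau_EN": 1, "SEA": 4},
    "Atlantic": {"NEA": 2, "SEA": 6},
    "Mediterranean": {"Kau_ME": 1, "SEA": 3}
  },
  "site_patterns": [
    {"carriers": ["WS"], "n_sites": 117},
    {"carriers": ["Kau_ME"], "n_sites": 53},
    {"carriers": ["NEA", "WS"], "n_sites": 5},
    {"carriers": ["Kau_ME", "SEA"], "n_sites": 3},
    {"carriers": ["NEA", "SEA", "WS"], "n_sites": 2},
    {"carriers": ["Kau_ME", "NEA", "WS"], "n_sites": 4},
    {"carriers": ["Kau_ME", "SEA", "WS"], "n_sites": 1},
    {"carriers": ["Kau_ME", "NEA", "SEA"], "n_sites": 6},
    {"carriers": ["Kau_EN", "Kau_ME", "SEA"], "n_sites": 11},
    {"carriers": ["Kau_ME", "NEA", "SEA", "WS"], "n_sites": 131},
    {"carriers": ["Kau_EN", "Kau_ME", "NEA", "SEA"], "n_sites": 2}
  ]
}
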