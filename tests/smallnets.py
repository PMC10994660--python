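"""Small atom-mapped test networks exercising every structural feature.

Each has at most 8 reactions and 6 carbons so that exhaustive isotopomer
enumeration stays cheap; used to validate the cumomer simulator.
"""

# -- small test networks (<= 8 reactions, <= 6 carbons) ----------------

GLYCO8 = {
    "name": "glyco8",
    "metabolites": {"G6P": 6, "F6P": 6, "FBP": 6, "DHAP": 3, "GAP": 3, "PYR": 3, "LAC": 3},
    "externals": {"GLC": 6},
    "symmetric": [],
    "reactions": [
        {"name": "HK", "equation": "GLC/abcdef -> G6P/abcdef"},
        {"name": "PGI", "equation": "G6P/abcdef -> F6P/abcdef", "reversible": True},
        {"name": "PFK", "equation": "F6P/abcdef -> FBP/abcdef"},
        {"name": "ALD", "equation": "FBP/abcdef -> DHAP/cba + GAP/def", "reversible": True},
        {"name": "TPI", "equation": "DHAP/abc -> GAP/cba", "reversible": True},
        {"name": "LOW", "equation": "GAP/abc -> PYR/abc"},
        {"name": "LDH", "equation": "PYR/abc -> LAC/abc", "reversible": True},
        {"name": "OUT", "equation": "LAC/abc ->"},
    ],
    "substrate_labeling": {"GLC": [{"pattern": "111111", "fraction": 1.0}]},
}
GLYCO8_FLUX = {
    "HK": 100, "PGI": 100, "PFK": 100, "ALD": 100, "TPI": 100,
    "LOW": 200, "LDH": 200, "OUT": 200,
}

CONDENSE = {
    "name": "condense",
    "metabolites": {"T1": 3, "T2": 3, "H": 6},
    "externals": {"A": 3},
    "reactions": [
        {"name": "u1", "equation": "A/abc -> T1/abc"},
        {"name": "u2", "equation": "A/abc -> T2/cba"},
        {"name": "join", "equation": "T1/abc + T2/def -> H/abcdef"},
        {"name": "out", "equation": "H/abcdef ->"},
    ],
    "substrate_labeling": {
        "A": [{"pattern": "111", "fraction": 0.6}, {"pattern": "100", "fraction": 0.4}]
    },
}
CONDENSE_FLUX = {"u1": 1.0, "u2": 1.0, "join": 1.0, "out": 1.0}

SYMNET = {
    "name": "symnet",
    "metabolites": {"S": 4, "P": 4},
    "externals": {"A": 4},
    "symmetric": ["S"],
    "reactions": [
        {"name": "up", "equation": "A/abcd -> S/abcd"},
        {"name": "conv", "equation": "S/abcd -> P/abcd"},
        {"name": "out", "equation": "P/abcd ->"},
    ],
    "substrate_labeling": {"A": [{"pattern": "1100", "fraction": 1.0}]},
}
SYMNET_FLUX = {"up": 2.0, "conv": 2.0, "out": 2.0}

REVX = {
    "name": "revx",
    "metabolites": {"B": 2, "C": 2},
    "externals": {"A": 2, "D": 2},
    "reactions": [
        {"name": "upA", "equation": "A/ab -> B/ab"},
        {"name": "upD", "equation": "D/ab -> C/ab"},
        {"name": "BC", "equation": "B/ab -> C/ba", "reversible": True},
        {"name": "out", "equation": "C/ab ->"},
    ],
    "substrate_labeling": {
        "A": [{"pattern": "10", "fraction": 0.7}, {"pattern": "00", "fraction": 0.3}],
        "D": [{"pattern": "00", "fraction": 1.0}],
    },
}
REVX_FLUX = {"upA": 1.0, "upD": 0.5, "BC": 1.0, "out": 1.5}

RECYCLE = {
    "name": "recycle",
    "metabolites": {"M": 2, "C": 1, "N": 3, "Q": 2},
    "externals": {"X": 2, "CX": 1},
    "reactions": [
        {"name": "upX", "equation": "X/ab -> M/ab"},
        {"name": "upC", "equation": "CX/a -> C/a"},
        {"name": "comb", "equation": "M/ab + C/c -> N/abc"},
        {"name": "split", "equation": "N/abc -> Q/ab + C/c"},
        {"name": "qout", "equation": "Q/ab ->"},
        {"name": "nout", "equation": "N/abc ->"},
    ],
    "substrate_labeling": {
        "X": [{"pattern": "11", "fraction": 0.5}, {"pattern": "00", "fraction": 0.5}],
        "CX": [{"pattern": "0", "fraction": 1.0}],
    },
}
RECYCLE_FLUX = {"upX": 1.0, "upC": 0.2, "comb": 1.0, "split": 0.8, "qout": 0.8, "nout": 0.2}

SMALL_NETWORKS = [
    ("glyco8", GLYCO8, GLYCO8_FLUX, None),
    ("condense", CONDENSE, CONDENSE_FLUX, None),
    ("symnet", SYMNET, SYMNET_FLUX, None),
    ("revx", REVX, REVX_FLUX, {"BC": 2.0}),
    ("recycle", RECYCLE, RECYCLE_FLUX, None),
]
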