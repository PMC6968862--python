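"""Published decision-tree structures used as worked examples.

These encode the reported HA-vs-LA (alpha band, clustering coefficient)
and AA-vs-LA (theta band, clustering coefficient) models as explicit
split specs for replay through the rule machinery.
"""

# LA if (T3 > 0.73) or (T3 <= 0.73 and Cz <= 0.57) or (T3 <= 0.73 and Cz > 0.84)
HA_LA_TREE = {
    "feature": "T3", "threshold": 0.73,
    "le": {
        "feature": "Cz", "threshold": 0.57,
        "le": {"leaf": "LA"},
        "gt": {
            "feature": "Cz", "threshold": 0.84,
            "le": {"leaf": "HA"},
            "gt": {"leaf": "LA"},
        },
    },
    "gt": {"leaf": "LA"},
}

# LA if (P3 > 0.6 and Pz <= 0.8) or (P3 > 0.6 and Pz > 0.8 and F4 > 0.7)
AA_LA_TREE = {
    "feature": "P3", "threshold": 0.6,
    "le": {"leaf": "AA"},
    "gt": {
        "feature": "Pz", "threshold": 0.8,
        "le": {"leaf": "LA"},
        "gt": {
            "feature": "F4", "threshold": 0.7,
            "le": {"leaf": "AA"},
            "gt": {"leaf": "LA"},
        },
    },
}
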