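"""Published reference numbers used as test inputs and expected values.

Feature statistics are per-class mean/SD on the fraction scale (the log
timing variables are logs of a 0-100 percent).  Confusion matrices are the
published validation-set counts, rows = true class, columns = estimated
class, both ordered RF, MF, FF.
"""

# per-class FSA mean/SD, degrees
CLASS_FSA = {"FF": (-10.2, 6.6), "MF": (3.0, 2.8), "RF": (24.9, 8.0)}

# per-class feature mean/SD (fraction convention)
CLASS_FEATURE_STATS = {
    "FF": {
        "ir_fore": (0.962, 0.057), "ir_aft": (0.038, 0.057),
        "ir_fore_0_33": (0.925, 0.098), "ir_aft_0_33": (0.075, 0.099),
        "pf_fore": (0.958, 0.082), "pf_aft": (0.081, 0.123),
        "rfd_fore": (0.883, 0.128), "rfd_aft": (0.145, 0.165),
        "ln_pct_rfd_fore": (2.69, 0.55), "ln_pct_rfd_aft": (2.72, 0.41),
    },
    "MF": {
        "ir_fore": (0.893, 0.070), "ir_aft": (0.106, 0.070),
        "ir_fore_0_33": (0.772, 0.129), "ir_aft_0_33": (0.228, 0.129),
        "pf_fore": (0.933, 0.061), "pf_aft": (0.222, 0.134),
        "rfd_fore": (0.700, 0.208), "rfd_aft": (0.405, 0.220),
        "ln_pct_rfd_fore": (2.27, 0.33), "ln_pct_rfd_aft": (2.89, 0.35),
    },
    "RF": {
        "ir_fore": (0.654, 0.115), "ir_aft": (0.346, 0.115),
        "ir_fore_0_33": (0.317, 0.163), "ir_aft_0_33": (0.682, 0.163),
        "pf_fore": (0.770, 0.115), "pf_aft": (0.599, 0.153),
        "rfd_fore": (0.492, 0.162), "rfd_aft": (0.912, 0.110),
        "ln_pct_rfd_fore": (2.43, 0.23), "ln_pct_rfd_aft": (3.25, 0.26),
    },
}

# published validation-set confusion matrices (rows true RF/MF/FF,
# columns estimated RF/MF/FF)
CONFUSION_MR = [[621, 13, 0], [26, 46, 48], [5, 8, 280]]
CONFUSION_TREE = [[613, 21, 0], [14, 88, 18], [5, 6, 282]]
CONFUSION_FOREST = [[611, 23, 0], [16, 92, 12], [3, 8, 282]]

# published one-decimal metrics recomputable from the matrices above
REPORTED = {
    "mr": {
        "accuracy": 90.4,
        "recall": {"RF": 97.9, "FF": 95.6},
        "precision": {"MF": 68.7, "FF": 85.4},
    },
    "tree": {
        "accuracy": 93.9,
        "recall": {"MF": 73.3},
        "precision": {"FF": 94.0},
    },
    "forest": {
        "accuracy": 94.1,
        "recall": {"MF": 76.7},
        "precision": {"FF": 95.9},
    },
}
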