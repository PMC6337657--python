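"""Worked reference cases for the per-seed decision rule.

Published per-seed category fractions and hand-picked per-variety thresholds
for three commercial corn varieties (Haoyu21, Haihe78, Jindan10), together
with the expected decision path and final category under the rule:
unique threshold exceedance -> that category; multiple -> bigger fraction;
none -> smallest |fraction - threshold|.

Each case: (variety, sample_no, original_label, p, expected_path,
expected_category).  ``SUBTRACTION_CASES`` additionally carries the
|p - t| values quoted to 5 decimals for the minimum-difference rows
(one quoted value, Haoyu21 sample 51 category 1, is corrected here from a
printing error: 0.37 - 0.31313 is 0.05687).
"""

THRESHOLDS = {
    "haoyu21": (0.37, 0.32, 0.44),
    "haihe78": (0.55, 0.239, 0.45),
    "jindan10": (0.38, 0.385, 0.34),
}

# variety, sample, original label, fractions, expected path, expected category
DECISION_CASES = [
    # -- multiple-exceedance (bigger fraction) rows --------------------------
    ("haoyu21", 83, 2, (0.38833, 0.32435, 0.28732), "bigger_fraction", 1),
    ("haoyu21", 167, 3, (0.17004, 0.32591, 0.50405), "bigger_fraction", 3),
    ("haihe78", 122, 3, (0.22491, 0.26965, 0.50544), "bigger_fraction", 3),
    ("jindan10", 39, 1, (0.38468, 0.26813, 0.34719), "bigger_fraction", 1),
    ("jindan10", 135, 3, (0.38983, 0.21243, 0.39774), "bigger_fraction", 3),
    # -- no-exceedance (minimum |p - t|) rows --------------------------------
    ("haoyu21", 51, 1, (0.31313, 0.28535, 0.40152), "min_difference", 2),
    ("haoyu21", 86, 2, (0.32100, 0.31026, 0.36874), "min_difference", 2),
    ("haoyu21", 115, 2, (0.36018, 0.28308, 0.35673), "min_difference", 1),
    ("haoyu21", 116, 2, (0.36364, 0.26477, 0.37159), "min_difference", 1),
    # Haihe78 sample 83: the published table bolds category 1, but its own
    # smallest-|p - t| rule selects category 3 (0.03824 < 0.04479 < 0.15598);
    # the rule-consistent outcome is asserted.
    ("haihe78", 83, 2, (0.39402, 0.19421, 0.41176), "min_difference", 3),
    ("haihe78", 84, 2, (0.39179, 0.22754, 0.38067), "min_difference", 2),
    ("haihe78", 98, 2, (0.38179, 0.23726, 0.38095), "min_difference", 2),
    ("haihe78", 101, 2, (0.34878, 0.23059, 0.42063), "min_difference", 2),
    ("haihe78", 112, 2, (0.47799, 0.19227, 0.32974), "min_difference", 2),
    ("haihe78", 114, 2, (0.34722, 0.20313, 0.44965), "min_difference", 3),
    ("jindan10", 22, 1, (0.37094, 0.32401, 0.30505), "min_difference", 1),
    ("jindan10", 62, 2, (0.34061, 0.37212, 0.28727), "min_difference", 2),
    ("jindan10", 122, 3, (0.36697, 0.29702, 0.33601), "min_difference", 3),
    ("jindan10", 127, 3, (0.36983, 0.29603, 0.33414), "min_difference", 3),
    ("jindan10", 130, 3, (0.36148, 0.30871, 0.32982), "min_difference", 3),
    ("jindan10", 140, 3, (0.32400, 0.35688, 0.31912), "min_difference", 3),
]

# variety, sample, quoted |p - t| per category (5 decimals)
SUBTRACTION_CASES = [
    ("haoyu21", 51, (0.05687, 0.03465, 0.03848)),
    ("haoyu21", 86, (0.04900, 0.00974, 0.07126)),
    ("haoyu21", 115, (0.00982, 0.03692, 0.08327)),
    ("haoyu21", 116, (0.00636, 0.05523, 0.06841)),
    ("haihe78", 83, (0.15598, 0.04479, 0.03824)),
    ("haihe78", 84, (0.15821, 0.01146, 0.06933)),
    ("haihe78", 98, (0.16821, 0.00174, 0.06905)),
    ("haihe78", 101, (0.20122, 0.00841, 0.02937)),
    ("haihe78", 112, (0.07201, 0.04673, 0.12026)),
    ("haihe78", 114, (0.20278, 0.03587, 0.00035)),
    ("jindan10", 22, (0.00906, 0.06099, 0.03495)),
    ("jindan10", 62, (0.03939, 0.01288, 0.05273)),
    ("jindan10", 122, (0.01303, 0.08798, 0.00399)),
    ("jindan10", 127, (0.01017, 0.08897, 0.00586)),
    ("jindan10", 130, (0.01852, 0.07629, 0.01018)),
    ("jindan10", 140, (0.05600, 0.02812, 0.02088)),
]

# The four Haoyu21 seeds with no exceeded threshold, in table order, with the
# original labels (1, 2, 2, 2); the rule assigns (2, 2, 1, 1) so three of the
# four end up misclassified.
HAOYU21_UNCERTAIN = {
    "samples": (51, 86, 115, 116),
    "original": (1, 2, 2, 2),
    "decided": (2, 2, 1, 1),
    "n_misclassified": 3,
}


def fractions_of(variety: str, sample: int):
    for v, s, _orig, p, _path, _cat in DECISION_CASES:
        if v == variety and s == sample:
            return p
    raise KeyError((variety, sample))
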