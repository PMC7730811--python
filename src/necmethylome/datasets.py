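"""Published worked-example inputs.

Element-stratified LM/IM/HM CpG site counts from a published WGBS study
of intestinal epithelium in surgical NEC (ileum and colon, NEC vs
non-NEC), together with the chi-square statistics that study printed,
and the printed counts of its methylation–expression directionality
analysis.  These serve as exact-input worked examples: feeding the
counts to :func:`necmethylome.profile.class_contingency_test` should
reproduce the printed statistics up to their rounding.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_class_counts",
    "REFERENCE_CHI_SQUARE",
    "REFERENCE_PERCENTAGES",
    "REFERENCE_DIRECTIONALITY",
]

# (element class) -> ((NEC LM, IM, HM), (non-NEC LM, IM, HM))
_ILEUM = {
    "Promoter": ((37570, 67544, 71628), (37809, 67963, 70970)),
    "Exonic": ((11252, 105227, 124986), (11276, 108315, 121874)),
    "Intronic": ((83095, 1880459, 2483522), (84504, 1949492, 2413080)),
    "CpG Island": ((14248, 6478, 10611), (14297, 6496, 10544)),
    "CpG Shore": ((55456, 125323, 168110), (55885, 124102, 168902)),
    "Enhancer": ((895, 5807, 5047), (910, 5913, 4926)),
    "Intergenic": ((80112, 2462179, 2264520), (82289, 2595021, 2129501)),
    "CpG Island + CpG Shore": ((69704, 131801, 178721), (70182, 130598, 179446)),
    "Exons + Introns": ((94347, 1985686, 2608508), (95780, 2057807, 2534954)),
    "All": ((205779, 4378720, 5074456), (208548, 4618095, 4832312)),
}
_COLON = {
    "Promoter": ((37158, 66839, 72745), (41311, 71457, 63974)),
    "Exonic": ((11149, 103599, 126717), (12921, 123568, 104976)),
    "Intronic": ((78867, 1849085, 2519124), (110129, 2196549, 2140398)),
    "CpG Island": ((14441, 6607, 10289), (14521, 6651, 10165)),
    "CpG Shore": ((54460, 123299, 171130), (62519, 129751, 156619)),
    "Enhancer": ((913, 5830, 5006), (1095, 6339, 4315)),
    "Intergenic": ((72468, 2472995, 2261348), (106195, 2850249, 1850367)),
    "CpG Island + CpG Shore": ((68901, 129906, 181419), (77040, 136402, 166784)),
    "Exons + Introns": ((90016, 1952684, 2645841), (123050, 2320117, 2245374)),
    "All": ((191444, 4407199, 5060312), (261637, 5166249, 4231069)),
}

# chi-square values as printed (df = 2 throughout)
REFERENCE_CHI_SQUARE = {
    "ileum": {
        "Promoter": 5.12,
        "Exonic": 83.9,
        "Intronic": 2270.0,
        "CpG Island": 0.32,
        "CpG Shore": 9.49,
        "Enhancer": 2.55,
        "Intergenic": 7668.0,
        "CpG Island + CpG Shore": 8.62,
        "Exons + Introns": 2349.0,
        "All": 12306.0,
    },
    "colon": {
        "Promoter": 937.0,
        "Exonic": 3926.0,
        "Intronic": 65796.0,
        "CpG Island": 1.1,
        "CpG Shore": 1362.0,
        "Enhancer": 89.0,
        "Intergenic": 74182.0,
        "CpG Island + CpG Shore": 1228.0,
        "Exons + Introns": 69507.0,
        "All": 145070.0,
    },
}

# printed percentages per condition (NEC then non-NEC, LM/IM/HM)
REFERENCE_PERCENTAGES = {
    ("ileum", "All"): ((2.1, 45.3, 52.5), (2.2, 47.8, 50.0)),
    ("ileum", "Promoter"): ((21.3, 38.2, 40.5), (21.4, 38.5, 40.2)),
    ("ileum", "CpG Island"): ((45.5, 20.7, 33.9), (45.6, 20.7, 33.6)),
    ("colon", "All"): ((2.0, 45.6, 52.4), (2.7, 53.5, 43.8)),
    ("colon", "Promoter"): ((21.0, 37.8, 41.2), (23.4, 40.4, 36.2)),
}

# methylation-expression directionality counts printed by the study:
# colon: 739 DE genes overlapped a DMR; 505 were down in NEC (68.3%),
# of which 428 had hypermethylated promoters (84.8%); 153 of 234
# up-genes were hypermethylated (65.4%).  ileum DE: 649 up (75.7%),
# 208 down (24.3%).
REFERENCE_DIRECTIONALITY = {
    "colon_overlap_total": 739,
    "colon_down": 505,
    "colon_down_hyper": 428,
    "colon_up": 234,
    "colon_up_hyper": 153,
    "ileum_de_up": 649,
    "ileum_de_down": 208,
}


def reference_class_counts(tissue: str) -> pd.DataFrame:
    """Published LM/IM/HM counts per element class for one tissue.

    Columns: element_class, n_LM_nec ... n_HM_ctrl.
    """
    src = {"ileum": _ILEUM, "colon": _COLON}[tissue]
    rows = []
    for cls, (nec, ctrl) in src.items():
        rows.append(
            {
                "element_class": cls,
                "n_LM_nec": nec[0], "n_IM_nec": nec[1], "n_HM_nec": nec[2],
                "n_LM_ctrl": ctrl[0], "n_IM_ctrl": ctrl[1], "n_HM_ctrl": ctrl[2],
            }
        )
    return pd.DataFrame(rows)
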