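"""Published reference values for the Lower Mississippi Basin (LMB) fauna.

The 3D body-shape study of the LMB fish fauna (232 specimens, 166 species,
11 landmarks) reported a per-landmark weighted eigenvector-magnitude
summary for its top six PCs, per-PC variance percentages, and an
anatomical-axis decomposition of total shape disparity.  Those printed
values are collected here so that worked examples and consistency checks
can feed them through the package's own arithmetic.
"""

from __future__ import annotations

import numpy as np

from .contribution import ContributionTable

#: per-PC percentage of total shape variance (PC1..PC6); PC6 is implied by
#: the reported PC4-6 block total of 14.4%
LMB_VARIANCE_PERCENTAGES = (51.1, 15.9, 13.4, 6.4, 5.1, 2.9)

#: anatomical-axis percentages of total body-shape variance
LMB_AXIS_PERCENTAGES = {
    "dorsoventral": 59.4,   # depth
    "anteroposterior": 31.1,  # length
    "mediolateral": 9.5,    # width
}

#: published weighted eigenvector magnitudes, landmark -> (L#, PC1..PC6),
#: to the 3 decimals printed
LMB_EIGENVECTOR_MAGNITUDES: dict[str, tuple[int, tuple[float, ...]]] = {
    "DF anterior insertion": (7, (0.312, 0.093, 0.090, 0.002, 0.011, 0.007)),
    "Left P2": (4, (0.189, 0.067, 0.036, 0.015, 0.014, 0.005)),
    "Right P2": (10, (0.190, 0.066, 0.035, 0.015, 0.014, 0.005)),
    "AF anterior insertion": (5, (0.101, 0.041, 0.058, 0.047, 0.018, 0.007)),
    "Left P1": (3, (0.136, 0.028, 0.028, 0.018, 0.020, 0.012)),
    "Right P1": (9, (0.135, 0.029, 0.028, 0.017, 0.021, 0.011)),
    "Tip snout": (1, (0.121, 0.019, 0.031, 0.031, 0.027, 0.012)),
    "Left Hypural": (6, (0.099, 0.033, 0.026, 0.014, 0.007, 0.003)),
    "Right Hypural": (11, (0.099, 0.033, 0.026, 0.014, 0.007, 0.002)),
    "Right eye": (8, (0.074, 0.032, 0.009, 0.007, 0.008, 0.006)),
    "Left eye": (2, (0.074, 0.031, 0.008, 0.005, 0.008, 0.006)),
}

#: landmark sets reported as dominating each of the first three PCs
LMB_PC_GROUPS = {
    1: ("DF anterior insertion", "Left P1", "Right P1", "Left P2", "Right P2"),
    2: ("DF anterior insertion", "AF anterior insertion", "Left P2", "Right P2"),
    3: ("DF anterior insertion", "AF anterior insertion", "Left P2", "Right P2"),
}

#: published percentages for those landmark sets (PC -> percent of that PC)
LMB_PC_GROUP_PERCENTAGES = {1: 62.8, 2: 56.6, 3: 58.5}


def lmb_contribution_table() -> ContributionTable:
    """The published LMB weighted-magnitude summary as a ContributionTable.

    Magnitudes are the printed 3-decimal values (already variance-weighted);
    rows are in the published ranking order.  Weights are the per-PC
    variance proportions.
    """
    names = tuple(LMB_EIGENVECTOR_MAGNITUDES)
    numbers = tuple(v[0] for v in LMB_EIGENVECTOR_MAGNITUDES.values())
    mags = np.array([v[1] for v in LMB_EIGENVECTOR_MAGNITUDES.values()])
    weights = np.array(LMB_VARIANCE_PERCENTAGES) / 100.0
    return ContributionTable(names, numbers, mags, weights=weights)
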