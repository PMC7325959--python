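"""Published reference tables for the three-group leukoaraiosis cohort.

These are the group-level effective-connectivity statistics reported for
the study design this package emulates (normal controls n=35, vascular
cognitive impairment no dementia n=32, vascular dementia n=20; ten
resting-state networks). They serve as fixed inputs for reproducing the
downstream degree summaries and for consistency checks — not as outputs of
this package.

All matrices are one-sample t statistics in the column-causes-row
orientation: the cell in row r, column c tests the directed edge c -> r.
Diagonals are undefined (NaN).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RSN_LABELS = ("PVN", "SVN", "AN", "SMN", "aDMN", "pDMN", "SN", "DAN",
              "lWMN", "rWMN")

GROUP_SIZES = {"NC": 35, "LA-VCIND": 32, "LA-VaD": 20}

_NAN = np.nan

# one-sample t per edge, vascular-dementia group (n = 20)
_LAVAD_T = [
    [_NAN, -1.992, -0.916, 2.504, 1.676, -0.834, -0.654, -3.004, 1.250, 0.968],
    [0.257, _NAN, -0.279, 2.332, -0.248, 0.343, 1.098, -1.986, -0.495, 1.825],
    [0.074, -1.702, _NAN, 0.724, 2.826, -2.485, -1.333, 2.463, 1.139, -0.469],
    [1.099, -2.875, 1.600, _NAN, 1.510, -2.374, -1.707, 1.482, 0.242, 1.520],
    [-0.778, -0.665, 1.266, 0.154, _NAN, 1.551, 0.652, -1.565, -0.886, 2.665],
    [1.239, -1.340, 0.240, 2.211, -0.283, _NAN, 0.690, -5.036, -0.309, 1.773],
    [1.085, -2.438, 0.313, 1.234, -1.252, 0.477, _NAN, -1.743, 1.398, 0.629],
    [3.937, -2.757, -0.701, 1.196, 0.042, -0.774, 0.917, _NAN, 0.287, 2.017],
    [0.512, -0.346, -0.235, 1.372, -1.328, 2.116, -0.064, -2.717, _NAN, 0.875],
    [0.287, -0.948, 0.545, 0.761, -3.014, 2.639, 1.572, -2.938, 1.040, _NAN],
]

# one-sample t per edge, vascular cognitive impairment group (n = 32)
_LAVCIND_T = [
    [_NAN, -3.918, 0.387, 1.525, 4.309, -3.106, -1.689, 0.463, 0.725, 1.660],
    [2.674, _NAN, 0.566, 1.109, 3.874, -3.015, -0.610, -0.440, 3.163, 2.013],
    [-0.216, -3.557, _NAN, 2.414, 3.104, -2.171, -1.830, 1.848, 1.431, -1.180],
    [1.582, -3.323, 1.677, _NAN, 3.716, -3.845, -1.409, 0.627, 1.563, 0.884],
    [1.795, -3.885, -0.042, 0.755, _NAN, 1.513, -0.607, -2.919, 1.008, 2.054],
    [2.206, -2.621, -0.534, 1.198, -0.950, _NAN, -1.044, -2.840, -0.819, 1.992],
    [2.023, -4.093, 1.354, 1.545, -0.871, 1.092, _NAN, -1.788, 0.847, 0.941],
    [2.441, -4.171, -0.988, 0.540, -0.153, -1.367, 0.142, _NAN, 0.538, 3.076],
    [2.690, -3.726, -0.437, 1.412, -2.835, 1.182, 0.483, -3.260, _NAN, 1.840],
    [2.274, -3.764, 0.510, 0.967, -4.043, 2.466, 0.451, -4.214, 1.373, _NAN],
]

# one-sample t per edge, normal-control group (n = 35)
_NC_T = [
    [_NAN, -5.849, 0.418, 2.436, 2.338, -1.974, 0.263, -2.967, 1.707, 0.884],
    [3.116, _NAN, 2.003, 1.598, 3.838, -1.034, 0.202, -2.030, 1.443, 1.962],
    [1.248, -3.752, _NAN, 2.517, 2.237, -1.969, -0.965, -0.517, 1.896, -0.138],
    [1.295, -3.159, 1.676, _NAN, 3.053, -2.897, -1.789, -0.669, 1.902, 1.082],
    [1.831, -5.127, 1.770, 0.826, _NAN, 2.050, -0.109, -3.858, 1.697, 2.506],
    [2.551, -5.688, 2.103, 1.949, -1.043, _NAN, 0.478, 5.481, 1.610, 1.346],
    [1.327, -4.287, 1.598, 1.934, -1.197, 1.998, _NAN, -3.591, 1.686, -0.220],
    [2.539, -4.695, 1.133, 2.188, -1.200, 1.005, 0.841, _NAN, 2.606, 1.382],
    [2.640, -4.580, 0.950, 1.427, -2.226, 2.010, 1.246, -5.848, _NAN, 0.495],
    [1.591, -4.974, 2.081, 1.937, -3.713, 3.401, 2.804, -5.546, 1.877, _NAN],
]


def t_matrix(group: str) -> pd.DataFrame:
    """Published per-edge one-sample t matrix for a group
    ('NC', 'LA-VCIND' or 'LA-VaD'), column-causes-row orientation."""
    data = {"NC": _NC_T, "LA-VCIND": _LAVCIND_T, "LA-VaD": _LAVAD_T}[group]
    return pd.DataFrame(np.asarray(data, dtype=float),
                        index=list(RSN_LABELS), columns=list(RSN_LABELS))


# group-difference summary for the four altered edges: per-group coefficient
# mean +/- SD, ANCOVA F and p (age and sex adjusted), Bonferroni post hoc p
GROUP_DIFFERENCE_TABLE = pd.DataFrame(
    [
        {"source": "DAN", "target": "PVN",
         "mean_LA-VaD": -0.175, "sd_LA-VaD": 0.261,
         "mean_LA-VCIND": 0.012, "sd_LA-VCIND": 0.150,
         "mean_NC": -0.083, "sd_NC": 0.166,
         "F": 6.360, "p": 0.003,
         "posthoc_LA-VaD_vs_NC": 0.118, "posthoc_LA-VCIND_vs_NC": 0.016,
         "posthoc_LA-VaD_vs_LA-VCIND": 0.002},
        {"source": "DAN", "target": "pDMN",
         "mean_LA-VaD": -0.203, "sd_LA-VaD": 0.181,
         "mean_LA-VCIND": -0.079, "sd_LA-VCIND": 0.158,
         "mean_NC": -0.147, "sd_NC": 0.158,
         "F": 3.709, "p": 0.029,
         "posthoc_LA-VaD_vs_NC": 0.228, "posthoc_LA-VCIND_vs_NC": 0.086,
         "posthoc_LA-VaD_vs_LA-VCIND": 0.012},
        {"source": "SVN", "target": "aDMN",
         "mean_LA-VaD": -0.021, "sd_LA-VaD": 0.140,
         "mean_LA-VCIND": -0.127, "sd_LA-VCIND": 0.186,
         "mean_NC": -0.126, "sd_NC": 0.145,
         "F": 3.359, "p": 0.040,
         "posthoc_LA-VaD_vs_NC": 0.012, "posthoc_LA-VCIND_vs_NC": 0.972,
         "posthoc_LA-VaD_vs_LA-VCIND": 0.032},
        {"source": "aDMN", "target": "SVN",
         "mean_LA-VaD": -0.012, "sd_LA-VaD": 0.216,
         "mean_LA-VCIND": 0.095, "sd_LA-VCIND": 0.138,
         "mean_NC": 0.085, "sd_NC": 0.131,
         "F": 3.273, "p": 0.043,
         "posthoc_LA-VaD_vs_NC": 0.042, "posthoc_LA-VCIND_vs_NC": 0.768,
         "posthoc_LA-VaD_vs_LA-VCIND": 0.034},
    ]
)
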