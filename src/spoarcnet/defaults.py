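"""Published parameter tables used as generator and model defaults.

The seven level-2 cognitive measures are abbreviated throughout the package:

========  =====================================================  =========
symbol    meaning                                                units
========  =====================================================  =========
boa       breadth of attention                                   cm
exo       exogenous attention-orienting cueing effect            ms
endo      endogenous attention-orienting cueing effect           ms
viwm      verbal item working-memory capacity                    proportion
vsowm     verbal serial-order working-memory capacity            proportion
siwm      spatial item working-memory capacity                   proportion
ssowm     spatial serial-order working-memory capacity           proportion
========  =====================================================  =========
"""

from __future__ import annotations

import numpy as np

#: order in which the cognitive measures appear in every matrix/table
COGNITIVE_MEASURES = ("boa", "exo", "endo", "viwm", "vsowm", "siwm", "ssowm")

#: level-2 marginal summaries: symbol -> (mean, sd, min, max)
L2_MARGINALS = {
    "boa": (77.15, 11.31, 28.70, 88.30),
    "exo": (33.54, 34.49, -64.01, 132.05),
    "endo": (36.52, 35.97, -42.04, 149.45),
    "viwm": (0.70, 0.13, 0.32, 0.96),
    "vsowm": (0.65, 0.18, 0.21, 0.97),
    "siwm": (0.81, 0.16, 0.29, 1.00),
    "ssowm": (0.66, 0.19, 0.27, 1.00),
}

# Spearman rank correlations among the seven cognitive measures
# (row/column order = COGNITIVE_MEASURES; lower triangle mirrored).
L2_SPEARMAN = np.array(
    [
        # boa    exo    endo   viwm   vsowm  siwm   ssowm
        [1.00,  0.00, -0.02,  0.05,  0.03, -0.10, -0.07],
        [0.00,  1.00,  0.20, -0.21, -0.22, -0.18, -0.22],
        [-0.02, 0.20,  1.00,  0.05,  0.03,  0.09,  0.00],
        [0.05, -0.21,  0.05,  1.00,  0.59,  0.32,  0.31],
        [0.03, -0.22,  0.03,  0.59,  1.00,  0.30,  0.40],
        [-0.10, -0.18, 0.09,  0.32,  0.30,  1.00,  0.66],
        [-0.07, -0.22, 0.00,  0.31,  0.40,  0.66,  1.00],
    ]
)

#: fixed-effect estimates of the reaction-time mixed model, gamma symbol -> ms
FIXED_EFFECTS = {
    # level-1 trial terms
    "g00": 1210.44,   # intercept
    "g10": 32.17,     # Hand (+1 right / -1 left)
    "g20": -37.37,    # Position (1..5)
    "g30": -23.27,    # Hand x Position (the SPoARC slope term)
    "g40": -69.63,    # Task (1 consonant / 2 color)
    "g50": 11.27,     # Task x Hand x Position
    # level-2 cognitive main effects (grand-mean-centered predictors)
    "g01": 0.99,      # boa
    "g02": 1.20,      # exo
    "g03": -0.61,     # endo
    "g05": 58.34,     # viwm
    "g06": 183.36,    # vsowm
    "g04": 39.16,     # siwm
    "g07": -114.90,   # ssowm
    # level-2 demographic controls (uncentered)
    "g08": 119.40,    # handedness (1 left / 2 right)
    "g09": 30.76,     # altL (0/1)
    "g010": 7.68,     # school code
    "g011": -29.56,   # education years
    "g012": 66.99,    # gender (1 male / 2 female)
    # cross-level interactions: measure x Hand x Position
    "g31": 0.13,      # boa
    "g32": -0.02,     # exo
    "g33": 0.02,      # endo
    "g35": 9.72,      # viwm
    "g36": -19.37,    # vsowm
    "g34": -24.25,    # siwm
    "g37": 17.84,     # ssowm
    "g347": -100.39,  # siwm x ssowm x Hand x Position
}

#: residual (level-1) variance, ms^2
SIGMA2 = 76098.40

#: by-participant random-effect covariance over
#: (intercept, Hand x Position, Task, Task x Hand x Position), ms^2
TAU = np.array(
    [
        [100786.00, -5425.88, -41676.41, 3360.10],
        [-5425.88, 1001.40, 2256.99, -574.26],
        [-41676.41, 2256.99, 26267.80, -1531.56],
        [3360.10, -574.26, -1531.56, 357.20],
    ]
)

#: names of the random-effect columns, in TAU's order
RANDOM_TERMS = ("intercept", "hand_position", "task", "task_hand_position")

#: demographic generator settings (cohort of 160: 149 right-handed,
#: 87 female, 6 exposed to right-to-left or spatially expressed languages)
DEMOGRAPHICS = {
    "p_right_handed": 149 / 160,
    "p_female": 87 / 160,
    "p_altL": 6 / 160,
    "p_school2": 0.30,
    "education_mean": 13.5,
    "education_sd": 1.5,
    "education_range": (12, 18),
}

#: item-probe trial-count interval per participant (correct YES trials)
TRIALS_PER_PARTICIPANT = (44, 79)

#: number of participants in the behavioral cohort
N_PARTICIPANTS = 160

#: graph density retained when thresholding connectivity matrices
EDGE_DENSITY = 0.1147

#: node counts of the analyzed networks (whole brain and function-specific)
NETWORK_SIZES = {
    "whole_brain": 84,
    "vsowm_attention": 66,
    "vsowm_siwm_ssowm": 72,
    "vsowm": 52,
    "attention": 56,
    "siwm": 55,
    "ssowm": 46,
}

#: reaction-time trimming windows (ms) per task family
RT_WINDOWS = {
    "boa": (100.0, 3000.0),
    "cueing": (100.0, 1200.0),
    "wm": (100.0, 3000.0),
    "item_probe": (100.0, 3000.0),
}
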