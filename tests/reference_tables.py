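"""Published validation-report tables used as fixed input data.

These are the per-position values printed in the rig's published validation
study: robot-world origin reconstruction deviations for six bone-sample
mounting positions, normalized tool-center-point positions, TCP deviations
relative to the control-program setting, tool-length (LOT) determinations,
and the flexion-extension trajectory deviation summary.

``CELLS`` lists every printed summary cell as
``(table, column, statistic, printed_value, decimals)`` where ``statistic``
names a :class:`jointcal.SummaryStats` field.  Three printed cells are
internally inconsistent with their own printed per-position values (no
statistic of the column reproduces them); they are listed separately in
``INCONSISTENT_CELLS``.
"""

# Origin-reconstruction deviations (mm) per axis, positions 0-5.
ORIGIN_DEVIATIONS = {
    "xR": [-0.003, -0.002, 0.000, 0.001, 0.184, 0.001],
    "yR": [0.378, 0.667, 0.104, -0.159, -0.241, -0.089],
    "zR": [0.218, 0.126, -0.025, 0.041, 0.178, 0.005],
}

#: Stated bound on the origin deviations: "maximum values did not exceed ±0.7 mm".
ORIGIN_DEVIATION_BOUND = 0.7

# TCP position normalized to mounting position 0 (mm), positions 0-5.
TCP_NORMALIZED = {
    "xR": [1064.00, 1059.64, 1058.72, 1061.02, 1061.25, 1059.90],
    "yR": [97.02, 96.45, 95.69, 95.15, 95.07, 97.93],
    "zR": [-201.19, -200.66, -199.79, -201.05, -200.22, -199.14],
}

# TCP deviation vs the control-program setting (mm), mean-adjusted to zero.
TCP_DEVIATIONS = {
    "xR": [-0.393, -1.618, 0.380, 0.159, 0.360, 1.110],
    "yR": [-0.016, 0.651, -0.181, -0.497, -0.951, 0.995],
    "zR": [-0.100, 0.037, 0.486, -0.465, 0.148, -0.108],
}

# Tool-length determination (mm), positions 0-5.
LOT = {
    "xR": [25.737, 26.137, 25.777, 25.353, 25.380, 24.015],
    "yR": [-0.005, -1.822, -0.326, -1.013, -0.270, 0.963],
    "zR": [365.337, 365.124, 365.467, 365.626, 365.600, 366.347],
    "cad": [366.242, 366.063, 366.375, 366.505, 366.480, 367.135],
    "transform": [367.96, 367.69, 366.54, 367.37, 366.79, 367.10],
}

# Flexion-extension trajectory deviation summary (mm): manual vs robotic.
TRAJECTORY_SUMMARY = {
    "dX": {"average": 3.44, "max": 3.66, "min": 3.26},
    "dY": {"average": -0.36, "max": 0.24, "min": -0.59},
    "dZ": {"average": 0.17, "max": 1.50, "min": -1.57},
    "euclidean": {"average": 3.59, "max": 3.79, "min": 3.41},
}

TABLES = {
    "origin": ORIGIN_DEVIATIONS,
    "tcp_normalized": TCP_NORMALIZED,
    "tcp_deviation": TCP_DEVIATIONS,
    "lot": LOT,
}

# (table, column, statistic, printed value, printed decimals)
CELLS = [
    # origin table: mean / population SD / plain extremes, 3 decimals
    ("origin", "xR", "mean", 0.030, 3),
    ("origin", "yR", "mean", 0.110, 3),
    ("origin", "zR", "mean", 0.091, 3),
    ("origin", "xR", "sd", 0.069, 3),
    ("origin", "yR", "sd", 0.321, 3),
    ("origin", "xR", "max_value", 0.184, 3),
    ("origin", "yR", "max_value", 0.667, 3),
    ("origin", "zR", "max_value", 0.218, 3),
    ("origin", "xR", "min_value", -0.003, 3),
    ("origin", "yR", "min_value", -0.241, 3),
    ("origin", "zR", "min_value", -0.025, 3),
    # normalized TCP table: population SD / mean / plain extremes, 2 decimals
    ("tcp_normalized", "xR", "sd", 1.68, 2),
    ("tcp_normalized", "yR", "sd", 1.03, 2),
    ("tcp_normalized", "zR", "sd", 0.72, 2),
    ("tcp_normalized", "xR", "mean", 1060.76, 2),
    ("tcp_normalized", "yR", "mean", 96.22, 2),
    ("tcp_normalized", "zR", "mean", -200.34, 2),
    ("tcp_normalized", "xR", "max_value", 1064.00, 2),
    ("tcp_normalized", "yR", "max_value", 97.93, 2),
    ("tcp_normalized", "zR", "max_value", -199.14, 2),
    ("tcp_normalized", "xR", "min_value", 1058.72, 2),
    ("tcp_normalized", "yR", "min_value", 95.07, 2),
    ("tcp_normalized", "zR", "min_value", -201.19, 2),
    # TCP deviation table: population SD / signed extreme deviations, 3 decimals
    ("tcp_deviation", "xR", "sd", 0.847, 3),
    ("tcp_deviation", "yR", "sd", 0.658, 3),
    ("tcp_deviation", "zR", "sd", 0.288, 3),
    ("tcp_deviation", "xR", "max_dev_pos", 1.110, 3),
    ("tcp_deviation", "yR", "max_dev_pos", 0.995, 3),
    ("tcp_deviation", "zR", "max_dev_pos", 0.486, 3),
    ("tcp_deviation", "xR", "min_dev_neg", 1.618, 3),
    ("tcp_deviation", "yR", "min_dev_neg", 0.951, 3),
    ("tcp_deviation", "zR", "min_dev_neg", 0.465, 3),
    # LOT table: mean / even-n median of deviations / extreme deviations
    ("lot", "xR", "mean", 25.400, 3),
    ("lot", "yR", "mean", -0.412, 3),
    ("lot", "zR", "mean", 365.584, 3),
    ("lot", "cad", "mean", 366.467, 3),
    ("lot", "transform", "mean", 367.24, 2),
    ("lot", "xR", "median_deviation", 0.159, 3),
    ("lot", "yR", "median_deviation", 0.114, 3),
    ("lot", "zR", "median_deviation", -0.050, 3),
    ("lot", "cad", "median_deviation", -0.039, 3),
    ("lot", "xR", "max_dev_pos", 0.737, 3),
    ("lot", "yR", "max_dev_pos", 1.375, 3),
    ("lot", "zR", "max_dev_pos", 0.763, 3),
    ("lot", "cad", "max_dev_pos", 0.668, 3),
    ("lot", "transform", "max_dev_pos", 0.72, 2),
    ("lot", "xR", "min_dev_neg", 1.385, 3),
    ("lot", "yR", "min_dev_neg", 1.410, 3),
    ("lot", "zR", "min_dev_neg", 0.459, 3),
    ("lot", "cad", "min_dev_neg", 0.404, 3),
]

# Printed cells that no statistic of their own printed column reproduces:
#  * origin zR SD: printed 0.126, recomputed population SD 0.090
#    (sample SD 0.098) — 0.126 happens to equal the position-1 value;
#  * lot/transform median deviation: printed 0.48, recomputed -0.007;
#  * lot/transform min deviation: printed 0.13, which matches the SMALLEST
#    |deviation| (0.128) — a different convention than every other column
#    (largest deviation below the mean, 0.702 here).
INCONSISTENT_CELLS = [
    ("origin", "zR", "sd", 0.126, 3),
    ("lot", "transform", "median_deviation", 0.48, 2),
    ("lot", "transform", "min_dev_neg", 0.13, 2),
]
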