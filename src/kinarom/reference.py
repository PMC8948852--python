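"""Printed reference measurements from the validation study.

These are inputs to reproduction checks, not outputs of this package:

* :data:`FIXED_ANGLE_TRIALS` — the fixed-angle bench validation: a
  goniometer-marked target angle and the mean of 30 sensor re-measurements,
  per side and movement (shoulder abduction at 30/60/90/120 deg, elbow
  flexion at 45/90/135/180 deg, both arms).
* The cohort characteristics table ships separately as
  ``data/reference_cohort.csv`` (see :func:`kinarom.records.load_reference_cohort`).
"""

from __future__ import annotations

#: (side, movement, reference_deg, measured_mean_deg)
FIXED_ANGLE_TRIALS: list[tuple[str, str, float, float]] = [
    ("right", "shoulder_abduction", 30.0, 30.549),
    ("right", "shoulder_abduction", 60.0, 59.994),
    ("right", "shoulder_abduction", 90.0, 90.425),
    ("right", "shoulder_abduction", 120.0, 120.546),
    ("right", "elbow_flexion", 45.0, 45.664),
    ("right", "elbow_flexion", 90.0, 90.624),
    ("right", "elbow_flexion", 135.0, 135.449),
    ("right", "elbow_flexion", 180.0, 180.548),
    ("left", "shoulder_abduction", 30.0, 30.257),
    ("left", "shoulder_abduction", 60.0, 60.590),
    ("left", "shoulder_abduction", 90.0, 90.514),
    ("left", "shoulder_abduction", 120.0, 120.876),
    ("left", "elbow_flexion", 45.0, 45.540),
    ("left", "elbow_flexion", 90.0, 90.504),
    ("left", "elbow_flexion", 135.0, 135.511),
    ("left", "elbow_flexion", 180.0, 180.603),
]

#: Printed error columns of the same table, keyed like FIXED_ANGLE_TRIALS.
#: The 60 deg right-shoulder row was printed from an unrounded mean and is
#: not exactly recomputable from the printed mean (0.006/0.01 recompute
#: vs 0.005/0.00 printed); it is flagged here for tests.
PRINTED_ERRORS: dict[tuple[str, str, float], tuple[float, float]] = {
    ("right", "shoulder_abduction", 30.0): (0.549, 1.83),
    ("right", "shoulder_abduction", 60.0): (0.005, 0.00),
    ("right", "shoulder_abduction", 90.0): (0.425, 0.47),
    ("right", "shoulder_abduction", 120.0): (0.546, 0.45),
    ("right", "elbow_flexion", 45.0): (0.664, 1.47),
    ("right", "elbow_flexion", 90.0): (0.624, 0.69),
    ("right", "elbow_flexion", 135.0): (0.449, 0.33),
    ("right", "elbow_flexion", 180.0): (0.548, 0.30),
    ("left", "shoulder_abduction", 30.0): (0.257, 0.85),
    ("left", "shoulder_abduction", 60.0): (0.590, 0.98),
    ("left", "shoulder_abduction", 90.0): (0.514, 0.57),
    ("left", "shoulder_abduction", 120.0): (0.876, 0.73),
    ("left", "elbow_flexion", 45.0): (0.540, 1.20),
    ("left", "elbow_flexion", 90.0): (0.504, 0.56),
    ("left", "elbow_flexion", 135.0): (0.511, 0.37),
    ("left", "elbow_flexion", 180.0): (0.603, 0.33),
}

#: Rows whose printed errors were derived from an unrounded mean and do
#: not recompute exactly from the printed mean.
INCONSISTENT_PRINTED_ROWS: frozenset[tuple[str, str, float]] = frozenset(
    {("right", "shoulder_abduction", 60.0)}
)
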