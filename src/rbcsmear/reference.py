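"""Published reference values for the 9-donor, 3-storage-week smear cohort.

The study cohort behind this pipeline comprises nine healthy donors whose red
blood cells were measured at storage weeks 0, 1 and 2: 27 donor-week samples,
each with a microfluidic rigidity score (RS), a deformability category, and a
2424 x 2424 px smear scan collection.  The raw images and sorting counts are
not publicly deposited; what is published are the summary tables below.  They
serve as fixed inputs for bookkeeping identities (dataset geometry, bin
counts) and for validating the aggregation arithmetic of the evaluation code.
"""

from __future__ import annotations

# --- Cohort geometry -------------------------------------------------------

N_DONORS = 9
N_STORAGE_WEEKS = 3
SCAN_SIZE_PX = 2424
TILE_SIZE_PX = 256
N_SCANS_TOTAL = 432  # large images captured across the 27 donor-week samples
TRAIN_TILES_PER_SMEAR = 10_000
TEST_TILES_PER_SMEAR = 2_000
VALIDATION_TILES_PER_SMEAR = 2_000  # held out of training for 5-fold CV

# RS span observed across the 27 donor-week samples; also the range used to
# express regression errors as percentage deviations.
RS_RANGE = (2.30, 3.56)

# --- Deformability category assignments (donor, week, bin 0..3) ------------
# Bin 0: RS < 2.50, bin 1: 2.50-2.74, bin 2: 2.75-2.99, bin 3: > 2.99.

DEFORMABILITY_BIN_ASSIGNMENTS: list[tuple[str, int, int]] = [
    ("1", 1, 0), ("1", 0, 1), ("1", 2, 2),
    ("2", 0, 0), ("2", 1, 1), ("2", 2, 3),
    ("3", 0, 0), ("3", 1, 0), ("3", 2, 2),
    ("4", 0, 0), ("4", 1, 1), ("4", 2, 2),
    ("5", 1, 2), ("5", 2, 2), ("5", 0, 3),
    ("6", 0, 1), ("6", 1, 3), ("6", 2, 3),
    ("7", 2, 2), ("7", 0, 3), ("7", 1, 3),
    ("8", 0, 2), ("8", 1, 2), ("8", 2, 3),
    ("9", 2, 1), ("9", 0, 2), ("9", 1, 2),
]

# --- Regression errors for RS prediction (all donors in train and test) ----

REGRESSION_MAE = 0.164
REGRESSION_MSE = 0.045
REGRESSION_RMSE = 0.212
REGRESSION_PEARSON_R = 0.708
MICROFLUIDIC_REPEATABILITY = 0.17  # same-donor, same-day re-run variation

# --- Storage-duration classification, donor-generalization protocol --------
# Row per held-out donor: (accuracy, precision, recall, F1); the first row is
# the all-donors upper bound where every donor appears in training and test.

ALL_DONOR_STORAGE_METRICS = (0.78, 0.869, 0.868, 0.868)

HELD_OUT_DONOR_METRICS: dict[str, tuple[float, float, float, float]] = {
    "1": (0.75, 0.835, 0.858, 0.833),
    "2": (0.60, 0.629, 0.640, 0.626),
    "3": (0.53, 0.557, 0.570, 0.561),
    "4": (0.55, 0.499, 0.545, 0.499),
    "5": (0.66, 0.628, 0.657, 0.639),
    "6": (0.57, 0.563, 0.569, 0.555),
    "7": (0.70, 0.667, 0.674, 0.669),
    "8": (0.58, 0.685, 0.676, 0.678),
    "9": (0.58, 0.557, 0.538, 0.544),
}
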