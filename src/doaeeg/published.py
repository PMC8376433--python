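"""Reference results reported for the original six-patient clinical study.

The clinical recordings behind this method are not redistributable, but the
study's summary tables are: per-patient epoch counts, the per-subject
confusion matrices of the full pipeline at its operating point (SPWVD, 16
gray levels, Mahalanobis KNN, augmentation m=35 / variance 0.1), the
per-subject accuracies, and the reported per-class sensitivities. They are
kept here so report arithmetic (accuracy = 100 * trace / total,
sensitivity = 100 * diagonal / row sum, averages, minima) can be
regression-tested against the published numbers, and so the acceptance
script can recompute those numbers from the raw counts.
"""

from __future__ import annotations

import numpy as np

SUBJECTS = ("1", "2", "3", "4", "5", "6")

#: epochs per label (rows D, A, S) per patient (columns 1..6)
EPOCH_COUNTS = {
    "D": (65, 125, 101, 31, 242, 303),
    "A": (336, 304, 333, 158, 275, 169),
    "S": (36, 207, 227, 73, 165, 74),
}

#: per-subject confusion counts; rows = actual (D, A, S), cols = predicted
CONFUSIONS = {
    "1": np.array([[60, 5, 0], [4, 320, 12], [0, 3, 33]]),
    "2": np.array([[119, 6, 0], [7, 285, 12], [0, 9, 198]]),
    "3": np.array([[94, 7, 0], [12, 311, 10], [0, 15, 212]]),
    "4": np.array([[30, 1, 0], [2, 151, 5], [0, 3, 70]]),
    "5": np.array([[235, 7, 0], [4, 264, 7], [0, 3, 162]]),
    "6": np.array([[293, 10, 0], [2, 163, 4], [0, 2, 72]]),
}

#: per-subject overall accuracy (%) with all channels, as reported
REPORTED_ACCURACY = {
    "1": 94.5, "2": 94.65, "3": 93.34, "4": 95.8, "5": 96.92, "6": 96.7,
}

REPORTED_AVERAGE_ACCURACY = 95.32
REPORTED_MIN_ACCURACY = 93.34

#: reported per-class sensitivities (%) per subject, order (D, A, S)
REPORTED_SENSITIVITY = {
    "1": (92.31, 95.24, 91.67),
    "2": (95.2, 93.75, 95.65),
    "3": (93.07, 93.39, 93.39),
    "4": (96.77, 95.57, 95.89),
    "5": (97.11, 96.0, 98.18),
    "6": (96.69, 96.45, 97.29),
}
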