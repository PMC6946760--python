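"""Reference performance matrices from a published 11-movement benchmark.

These three row-percent performance matrices (rows = intended movement,
columns = detected movement, entries = average percentages across 20
subjects) come from a published forearm sEMG benchmark of the same
4-channel, 2000 Hz, 11-class protocol this package implements.  They are
the best combinations per feature domain: the proposed time-domain set
with the Gaussian maximum-likelihood classifier (``FS_MLE``), the
10 Hz-binned frequency-energy feature with k-nearest neighbour
(``FE_KNN``), and the wavelet-packet log-RMS feature with a multilayer
perceptron (``LOGRMS_MLP``).  Their diagonal means — 97.43%, 90.0% and
95.47% — are the printed "Average" statistics that
:func:`emgpr.classify.mean_recall` recomputes.
"""

from __future__ import annotations

import numpy as np

from .classify import ConfusionMatrix

__all__ = ["BENCHMARK_CLASSES", "FS_MLE", "FE_KNN", "LOGRMS_MLP", "benchmark_matrices"]

BENCHMARK_CLASSES = (
    "open hand", "close hand", "flex hand", "extend hand", "pronation",
    "supination", "side grip", "fine grip", "agree", "pointer", "rest",
)

FS_MLE = np.array([
    [98.36, 0.16, 0.08, 0.00, 0.08, 0.25, 0.16, 0.08, 0.25, 0.41, 0.16],
    [0.25, 97.79, 0.08, 0.08, 0.00, 0.00, 0.66, 0.00, 0.66, 0.33, 0.16],
    [0.16, 0.00, 99.26, 0.00, 0.33, 0.00, 0.00, 0.00, 0.00, 0.16, 0.08],
    [0.16, 0.08, 0.00, 99.51, 0.00, 0.00, 0.08, 0.16, 0.00, 0.00, 0.00],
    [0.49, 0.00, 0.16, 0.00, 98.93, 0.08, 0.00, 0.08, 0.08, 0.16, 0.00],
    [0.33, 0.08, 0.00, 0.16, 0.08, 98.77, 0.16, 0.08, 0.16, 0.16, 0.00],
    [0.74, 0.49, 0.00, 0.08, 0.33, 0.00, 95.33, 0.90, 1.07, 1.07, 0.00],
    [0.66, 0.41, 0.08, 0.16, 1.23, 0.25, 1.88, 94.43, 0.33, 0.57, 0.00],
    [0.33, 0.81, 0.08, 0.00, 0.08, 0.33, 0.66, 0.16, 95.90, 1.64, 0.00],
    [0.25, 0.82, 0.25, 0.08, 0.25, 0.33, 0.33, 0.16, 1.31, 96.23, 0.00],
    [0.49, 0.25, 0.08, 0.00, 0.33, 0.00, 0.90, 0.16, 0.41, 0.16, 97.21],
])

FE_KNN = np.array([
    [87.46, 0.33, 0.00, 0.08, 1.64, 0.98, 1.97, 1.72, 1.97, 2.70, 1.15],
    [0.41, 85.66, 0.00, 0.33, 0.98, 0.25, 4.26, 2.62, 2.54, 2.30, 0.57],
    [0.66, 0.16, 97.46, 0.00, 0.49, 0.00, 0.08, 0.16, 0.00, 0.41, 0.33],
    [1.15, 0.74, 0.00, 95.25, 0.00, 0.00, 0.41, 0.57, 1.15, 0.00, 0.00],
    [3.28, 0.74, 0.33, 0.00, 88.11, 2.13, 1.56, 1.64, 1.15, 0.33, 0.00],
    [0.74, 0.25, 0.00, 0.00, 0.57, 90.33, 0.33, 2.21, 2.70, 1.72, 0.98],
    [1.64, 1.39, 0.00, 0.00, 0.82, 0.41, 84.43, 5.90, 2.30, 1.39, 1.64],
    [0.49, 1.39, 0.00, 0.00, 0.74, 0.66, 5.98, 86.39, 1.80, 0.66, 1.89],
    [1.39, 0.74, 0.00, 0.00, 0.00, 2.13, 1.39, 1.80, 88.28, 2.13, 1.15],
    [1.23, 1.56, 0.00, 0.00, 0.08, 1.64, 1.23, 3.03, 1.15, 88.20, 1.80],
    [0.08, 0.16, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 98.52],
])

LOGRMS_MLP = np.array([
    [95.33, 0.49, 0.16, 0.08, 0.25, 0.98, 0.25, 0.41, 0.57, 0.90, 0.57],
    [0.41, 95.66, 0.00, 0.08, 0.00, 0.66, 0.82, 0.57, 0.98, 0.41, 0.41],
    [0.25, 0.00, 98.28, 0.00, 0.49, 0.08, 0.08, 0.16, 0.16, 0.16, 0.33],
    [0.08, 0.08, 0.00, 98.93, 0.08, 0.08, 0.25, 0.49, 0.00, 0.00, 0.00],
    [0.25, 0.00, 0.08, 0.00, 98.11, 0.25, 0.33, 0.66, 0.16, 0.08, 0.08],
    [0.66, 0.49, 0.08, 0.00, 0.16, 96.39, 0.41, 0.66, 0.66, 0.25, 0.25],
    [0.74, 0.49, 0.00, 0.00, 0.49, 0.16, 91.31, 3.61, 0.82, 1.39, 0.98],
    [0.00, 0.66, 0.08, 0.08, 0.74, 0.25, 3.03, 93.36, 0.49, 0.90, 0.41],
    [0.66, 1.23, 0.16, 0.00, 0.08, 0.90, 0.49, 0.82, 93.28, 2.30, 0.08],
    [1.15, 0.41, 0.16, 0.00, 0.25, 0.49, 1.64, 0.98, 2.13, 91.80, 0.98],
    [0.16, 0.16, 0.16, 0.00, 0.00, 0.00, 0.74, 0.49, 0.00, 0.57, 97.70],
])


def benchmark_matrices() -> dict[str, ConfusionMatrix]:
    """The three reference matrices as :class:`ConfusionMatrix` objects."""
    return {
        "FS_MLE": ConfusionMatrix.from_percent(FS_MLE, BENCHMARK_CLASSES),
        "FE_KNN": ConfusionMatrix.from_percent(FE_KNN, BENCHMARK_CLASSES),
        "LOGRMS_MLP": ConfusionMatrix.from_percent(LOGRMS_MLP, BENCHMARK_CLASSES),
    }
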