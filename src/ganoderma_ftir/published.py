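"""Reported metrics from the original three-species Ganoderma ATR-FTIR study.

These printed values serve as inputs for convention cross-checks: the ten
per-repetition rows of the CNN random-segregation table (accuracy %,
sensitivity %, specificity %, macro precision, recall, F1), their printed
summary row, and the chemometric model triples.  They are reference data, not
outputs of this package.
"""

from __future__ import annotations

__all__ = [
    "RANDOM_SEGREGATION_RUNS",
    "RANDOM_SEGREGATION_MEAN",
    "RANDOM_SEGREGATION_SD",
    "RANDOM_SEGREGATION_CV",
    "OPLSDA_TRIPLE",
    "PCA_CLASS_TRIPLE",
    "OPLSDA_QUALITY",
]

#: columns: accuracy %, sensitivity %, specificity %, precision, recall, F1
RANDOM_SEGREGATION_RUNS: tuple[tuple[float, ...], ...] = (
    (88.98, 83.47, 91.73, 0.86, 0.84, 0.85),
    (91.82, 87.73, 93.87, 0.90, 0.88, 0.89),
    (85.16, 77.73, 88.87, 0.83, 0.78, 0.80),
    (90.67, 86.00, 93.00, 0.88, 0.86, 0.87),
    (91.24, 86.87, 93.43, 0.89, 0.87, 0.88),
    (90.67, 86.00, 93.00, 0.88, 0.86, 0.87),
    (88.22, 82.33, 91.17, 0.86, 0.82, 0.84),
    (89.78, 84.67, 92.33, 0.87, 0.85, 0.86),
    (89.56, 84.33, 92.17, 0.87, 0.84, 0.86),
    (92.27, 88.40, 94.20, 0.90, 0.89, 0.89),
)

#: printed summary row (same column order as the runs)
RANDOM_SEGREGATION_MEAN = (89.84, 84.75, 92.38, 0.87, 0.85, 0.86)
RANDOM_SEGREGATION_SD = (1.96, 2.95, 1.47, 0.02, 0.03, 0.03)
RANDOM_SEGREGATION_CV = (2.18, 3.48, 1.59, 2.30, 3.55, 2.96)

#: (accuracy %, sensitivity %, specificity %) of the two chemometric models
OPLSDA_TRIPLE = (98.61, 97.92, 98.96)
PCA_CLASS_TRIPLE = (98.31, 97.46, 98.73)

#: R2X, R2Y, Q2Y, R2Y-intercept, Q2Y-intercept, RMSEE, RMSECV, RMSEP
OPLSDA_QUALITY = {
    "r2x": 0.99,
    "r2y": 0.85,
    "q2y": 0.72,
    "r2y_intercept": 0.30,
    "q2y_intercept": -0.76,
    "rmsee": 0.21,
    "rmsecv": 0.26,
    "rmsep": 0.25,
}


def all_metric_triples() -> list[tuple[float, float, float]]:
    """All twelve printed (accuracy, sensitivity, specificity) triples."""
    triples = [(r[0], r[1], r[2]) for r in RANDOM_SEGREGATION_RUNS]
    triples.append(OPLSDA_TRIPLE)
    triples.append(PCA_CLASS_TRIPLE)
    return triples
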