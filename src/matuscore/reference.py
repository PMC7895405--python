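"""Published reference distributions for a 252-case B-CLPD cohort.

These are the printed cross-tabulations from the single-centre clinical
cohort (199 CLL, 53 non-CLL) against which the scoring arithmetic and the
accuracy statistics of this package are validated. They are inputs — score
histograms and per-subtype CD200 positivity counts — not outputs of this
package; the synthetic cohort in :mod:`matuscore.simulate` is designed to
emulate them.

Score histograms are mapped ``score -> number of cases``. The top row of
the published augmented-score table pools scores 5 and 6; it is stored at
score 5, which is order-preserving and therefore leaves every rank-based
statistic unchanged.
"""

from __future__ import annotations

import numpy as np

#: Cohort composition: diagnosis -> number of cases.
COHORT_COMPOSITION = {
    "CLL-typical": 189,
    "CLL-atypical": 10,
    "MCL": 20,
    "MZL": 17,
    "HCL": 8,
    "FL": 3,
    "OTHER": 5,
}

#: Published score cross-tabs: system -> {"CLL": {...}, "non_CLL": {...}}.
SCORE_CROSSTABS = {
    "classical": {
        "CLL": {5: 94, 4: 95, 3: 10},
        "non_CLL": {3: 7, 2: 19, 1: 18, 0: 9},
    },
    "augmented": {
        "CLL": {5: 189, 4: 10},
        "non_CLL": {4: 1, 3: 16, 2: 19, 1: 14, 0: 3},
    },
    "four_marker": {
        "CLL": {4: 187, 3: 12},
        "non_CLL": {3: 4, 2: 16, 1: 30, 0: 3},
    },
}

#: Per-subtype CD200 positivity at the >=30% cut: subtype -> (n_positive, n).
CD200_POSITIVE_COUNTS = {
    "CLL": (199, 199),
    "HCL": (5, 8),
    "MZL": (12, 17),
    "MCL": (0, 20),
    "FL": (1, 3),
    "OTHER": (2, 5),
}

#: Published per-subtype CD200 percent-positive median and range.
CD200_PERCENT_SUMMARY = {
    "CLL": (97.9, 50.6, 100.0),
    "HCL": (46.4, 0.9, 91.8),
    "MZL": (55.9, 0.4, 88.0),
    "MCL": (2.3, 0.1, 41.0),
    "FL": (1.7, 0.9, 70.6),
    "OTHER": (5.9, 1.9, 57.6),
}

#: Published per-subtype CD200 MFIR median and range.
CD200_MFIR_SUMMARY = {
    "CLL": (59.0, 39.3, 69.9),
    "HCL": (46.5, 1.5, 77.0),
    "MZL": (24.0, 1.3, 58.0),
    "MCL": (3.3, 0.7, 43.0),
    "FL": (3.0, 1.6, 43.0),
    "OTHER": (1.5, 1.0, 45.0),
}


def expand_crosstab(system: str) -> tuple[np.ndarray, np.ndarray]:
    """Expand a score cross-tab into per-case (scores, is_cll) arrays.

    Returns one score per case with a parallel boolean truth vector, suitable
    for :func:`matuscore.diagnostics.rank_auc` and friends.
    """
    tab = SCORE_CROSSTABS[system]
    scores: list[int] = []
    truth: list[bool] = []
    for group, flag in (("CLL", True), ("non_CLL", False)):
        for score, n in sorted(tab[group].items(), reverse=True):
            scores.extend([score] * n)
            truth.extend([flag] * n)
    return np.asarray(scores, dtype=float), np.asarray(truth, dtype=bool)
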