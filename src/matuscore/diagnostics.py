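"""Diagnostic-accuracy statistics for the scoring systems and single markers.

Implements the evaluation toolkit used on the cohort: 2x2 confusion counts
with CLL as the positive class, exact (Clopper-Pearson) binomial confidence
intervals for sensitivity/specificity, the tie-corrected rank AUC (the
normalised Mann-Whitney statistic — the probability that a random CLL case
outranks a random non-CLL case, with half-credit for ties) with a DeLong
interval, Youden-optimal ROC cutoffs, McNemar's test between paired scoring
systems and Mann-Whitney U for continuous marker comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

#: Discordant-pair count at or below which McNemar's test is exact.
MCNEMAR_EXACT_LIMIT = 25

#: Per-group size at or below which Mann-Whitney uses exact enumeration.
MWU_EXACT_LIMIT = 20


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts with CLL as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    def sensitivity(self) -> float:
        return self.tp / self.n_positive

    def specificity(self) -> float:
        return self.tn / self.n_negative


@dataclass(frozen=True)
class AccuracySummary:
    """Point estimates with two-sided 95% CIs for one classifier."""

    sensitivity: tuple[float, float, float]
    specificity: tuple[float, float, float]
    accuracy: tuple[float, float, float]
    auc: tuple[float, float, float]
    confusion: ConfusionTable


def confusion_counts(binary_calls, truth) -> ConfusionTable:
    """Tally calls against truth; both are boolean-like, CLL positive."""
    calls = np.asarray(binary_calls, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if calls.shape != t.shape:
        raise ValueError(f"length mismatch: {calls.shape} vs {t.shape}")
    return ConfusionTable(
        tp=int(np.count_nonzero(calls & t)),
        fp=int(np.count_nonzero(calls & ~t)),
        fn=int(np.count_nonzero(~calls & t)),
        tn=int(np.count_nonzero(~calls & ~t)),
    )


def proportion_ci(successes: int, n: int) -> tuple[float, float, float]:
    """Point estimate and exact Clopper-Pearson two-sided 95% interval."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= successes <= n):
        raise ValueError(f"successes {successes} outside [0, {n}]")
    lower, upper = proportion_confint(successes, n, alpha=0.05, method="beta")
    return (successes / n, float(lower), float(upper))


def rank_auc(scores, truth) -> float:
    """Tie-corrected rank AUC of scores for separating truth classes.

    AUC = [#(positive > negative) + 0.5 * #(ties)] / (n_pos * n_neg),
    computed via midranks so it is exactly the normalised Mann-Whitney
    statistic.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = stats.rankdata(s)
    u = ranks[t].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the rank AUC via placement values."""
    m, n = len(pos), len(neg)
    # V10[i] = P(pos_i > neg) with half-credit ties; V01[j] symmetric
    v10 = np.array(
        [((p > neg).sum() + 0.5 * (p == neg).sum()) / n for p in pos]
    )
    v01 = np.array(
        [((pos > q).sum() + 0.5 * (pos == q).sum()) / m for q in neg]
    )
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_ci(scores, truth) -> tuple[float, float, float]:
    """Rank AUC with a DeLong 95% confidence interval, clipped to [0, 1]."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    auc = rank_auc(s, t)
    var = _delong_variance(s[t], s[~t])
    half = 1.959963984540054 * np.sqrt(var)
    return (auc, float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def roc_optimal_cutoff(values, truth) -> tuple[float, float, float]:
    """Youden-optimal threshold for the rule ``value >= cutoff -> CLL``.

    Scans every achievable threshold (the unique observed values);
    maximises J = sensitivity + specificity - 1, breaking ties toward
    higher sensitivity and then toward the lower cutoff. Returns
    (cutoff, sensitivity, specificity) at the optimum.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if v.shape != t.shape:
        raise ValueError("values and truth must have equal length")
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    best = None
    for cut in np.unique(v):
        calls = v >= cut
        sens = np.count_nonzero(calls & t) / n_pos
        spec = np.count_nonzero(~calls & ~t) / n_neg
        j = sens + spec - 1.0
        key = (j, sens, -cut)
        if best is None or key > best[0]:
            best = (key, float(cut), float(sens), float(spec))
    return best[1], best[2], best[3]


def mcnemar_test(calls_a, calls_b, truth) -> float:
    """Two-sided McNemar p-value comparing paired classifier correctness.

    Exact binomial on the discordant pairs when b + c <= 25, otherwise
    chi-square with continuity correction; p = 1 with no discordant pairs.
    """
    a = np.asarray(calls_a, dtype=bool)
    b_calls = np.asarray(calls_b, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if not (a.shape == b_calls.shape == t.shape):
        raise ValueError("call vectors and truth must have equal length")
    correct_a = a == t
    correct_b = b_calls == t
    b = int(np.count_nonzero(correct_a & ~correct_b))
    c = int(np.count_nonzero(~correct_a & correct_b))
    n_disc = b + c
    if n_disc == 0:
        return 1.0
    if n_disc <= MCNEMAR_EXACT_LIMIT:
        return float(stats.binomtest(b, n_disc, 0.5).pvalue)
    chi2 = (abs(b - c) - 1.0) ** 2 / n_disc
    return float(stats.chi2.sf(chi2, df=1))


def mann_whitney(group_1, group_2) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both groups have at most 20 observations and no
    ties are present; otherwise the normal approximation with tie and
    continuity correction. Returns (U of group 1, p-value).
    """
    x = np.asarray(group_1, dtype=float)
    y = np.asarray(group_2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size <= MWU_EXACT_LIMIT and y.size <= MWU_EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def evaluate_binary(calls, truth, scores=None) -> AccuracySummary:
    """Full accuracy summary for one binary screen.

    ``scores`` (ordinal, optional) feed the rank AUC; when omitted the
    binary calls themselves are ranked.
    """
    table = confusion_counts(calls, truth)
    if table.n_positive == 0 or table.n_negative == 0:
        raise ValueError("both classes must be present for evaluation")
    n = table.n_positive + table.n_negative
    rank_scores = calls if scores is None else scores
    return AccuracySummary(
        sensitivity=proportion_ci(table.tp, table.n_positive),
        specificity=proportion_ci(table.tn, table.n_negative),
        accuracy=proportion_ci(table.tp + table.tn, n),
        auc=auc_ci(rank_scores, truth),
        confusion=table,
    )
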