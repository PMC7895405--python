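"""Immunophenotypic scoring systems for CLL vs other B-CLPD.

Three scores are computed from the per-sample marker quantification:

* classical 5-marker score (0-5): CD5, CD23, FMC7, CD79b, sIgM;
* CD200-augmented score (0-6): the classical score plus a CD200 point;
* simplified 4-marker score (0-4): CD5, CD23, sIgM, CD200.

Point rules (a point is one unit toward a CLL phenotype): CD5, CD23 and
CD200 score 1 when the positive B-cell population is >= 30% (boundary
inclusive); FMC7 and CD79b score 1 when it is strictly < 30%; sIgM scores
1 when its expression pattern is weak. CD200 may optionally be scored by
MFIR >= 18 instead of percent-positive.

Classification: score >= 4 is typical CLL, score 3 atypical CLL, <= 2
non-CLL; the binary diagnostic screen is score >= 4 for every system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .gating import MarkerResultSet
from .panel import (
    CLASSICAL_MARKERS,
    FOUR_MARKER_MARKERS,
    MFIR_CUTOFF,
    POSITIVITY_CUTOFF,
)

SYSTEMS = ("classical", "augmented", "four_marker")

_SCORE_RANGE = {"classical": 5, "augmented": 6, "four_marker": 4}


class ScoringError(ValueError):
    """Raised for missing markers or out-of-range scores."""


@dataclass(frozen=True)
class ScoreResult:
    """Scores, per-system classification and per-marker point breakdown."""

    sample_id: str
    points: Mapping[str, int]
    classical_score: int
    augmented_score: int
    four_marker_score: int
    classical_class: str
    augmented_class: str
    four_marker_class: str


def marker_points(
    results: MarkerResultSet, cd200_mode: str = "percent"
) -> dict[str, int]:
    """Score each marker 0/1 by its point rule.

    ``cd200_mode`` selects whether CD200 is scored by percent-positive
    (>= 30, the default) or by MFIR (>= 18).
    """
    if cd200_mode not in ("percent", "mfir"):
        raise ScoringError(f"unknown cd200_mode {cd200_mode!r}")
    needed = set(CLASSICAL_MARKERS) | {"CD200"}
    for marker in sorted(needed):
        if marker not in results.markers:
            raise ScoringError(f"marker {marker} missing from results")

    m = results.markers
    points = {
        "CD5": int(m["CD5"].percent_positive >= POSITIVITY_CUTOFF),
        "CD23": int(m["CD23"].percent_positive >= POSITIVITY_CUTOFF),
        "FMC7": int(m["FMC7"].percent_positive < POSITIVITY_CUTOFF),
        "CD79b": int(m["CD79b"].percent_positive < POSITIVITY_CUTOFF),
        "sIgM": int(m["sIgM"].pattern == "weak"),
    }
    if cd200_mode == "percent":
        points["CD200"] = int(m["CD200"].percent_positive >= POSITIVITY_CUTOFF)
    else:
        points["CD200"] = int(m["CD200"].mfir >= MFIR_CUTOFF)
    return points


def classical_score(points: Mapping[str, int]) -> int:
    """Classical 5-marker score: sum of the CD5/CD23/FMC7/CD79b/sIgM points."""
    return sum(int(points[m]) for m in CLASSICAL_MARKERS)


def cd200_augmented_score(points: Mapping[str, int]) -> int:
    """CD200-augmented score: classical score plus the CD200 point."""
    return classical_score(points) + int(points["CD200"])


def four_marker_score(points: Mapping[str, int]) -> int:
    """Simplified 4-marker score: CD5 + CD23 + sIgM + CD200 points."""
    return sum(int(points[m]) for m in FOUR_MARKER_MARKERS)


def classify_sample(score: int, system: str) -> str:
    """Map a score to typical-CLL (>=4), atypical-CLL (=3) or non-CLL (<=2)."""
    if system not in _SCORE_RANGE:
        raise ScoringError(f"unknown scoring system {system!r}")
    if not (0 <= score <= _SCORE_RANGE[system]):
        raise ScoringError(
            f"score {score} outside [0, {_SCORE_RANGE[system]}] for {system}"
        )
    if score >= 4:
        return "typical-CLL"
    if score == 3:
        return "atypical-CLL"
    return "non-CLL"


def is_cll_call(score: int) -> bool:
    """Binary diagnostic screen: score >= 4 calls CLL in every system."""
    return score >= 4


def score_sample(results: MarkerResultSet, cd200_mode: str = "percent") -> ScoreResult:
    """Compute all three scores and classifications for one sample."""
    points = marker_points(results, cd200_mode)
    cs = classical_score(points)
    aug = cd200_augmented_score(points)
    fm = four_marker_score(points)
    return ScoreResult(
        sample_id=results.sample_id,
        points=points,
        classical_score=cs,
        augmented_score=aug,
        four_marker_score=fm,
        classical_class=classify_sample(cs, "classical"),
        augmented_class=classify_sample(aug, "augmented"),
        four_marker_class=classify_sample(fm, "four_marker"),
    )
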