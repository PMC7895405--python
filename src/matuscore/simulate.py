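"""Synthetic listmode cohort generator.

Simulates per-patient flow-cytometry samples for a B-CLPD differential
cohort: 252 cases by default (189 typical CLL, 10 atypical CLL, 20 MCL,
17 MZL, 8 HCL, 3 FL, 5 other), each a stained event table plus a matched
isotype-control table on a linear 4-decade fluorescence scale.

Each case is drawn from a per-case :class:`DiagnosisTemplate`: bounded
percent-positive distributions per marker, log-normal positive-population
intensities, a CD45/SSC population mixture (lymphocytes, monocytes,
granulocytes, debris) and a B-cell fraction of lymphocytes. Case templates
are organised in fixed per-diagnosis design lists that reproduce the
published marker-point patterns: every CLL case carries the CD200 point,
exactly one non-CLL case (an HCL scoring 3 classically) reaches the
CD200-augmented score of 4, and all MCL templates keep CD200 well below
the 30% positivity boundary. Percent targets sit at least 5 points away
from the 30% decision boundary so downstream classification counts are
stable across seeds.

Randomness is reproducible: a single master seed plus the sample index
derive an independent per-sample stream, so any sample can be regenerated
in isolation.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import CLL_LABELS, DIAGNOSES, EVENT_COLUMNS, GATING_COLUMNS, PANEL_MARKERS

LN10 = math.log(10.0)

#: Default per-tube event count (the acquisition scale of the emulated assay).
DEFAULT_EVENTS_PER_SAMPLE = 20_000

#: Default cellular mixture of a leukemic PB/BM specimen.
MIXTURE_WEIGHTS = {
    "lymphocyte": 0.72,
    "monocyte": 0.10,
    "granulocyte": 0.08,
    "debris": 0.10,
}

#: Scatter and CD45 placement per population. CD45 is log10-normal; FSC/SSC
#: are truncated normals on an arbitrary 0-1000 linear scale. Lymphocytes are
#: CD45-bright/SSC-low; granulocytes CD45-dim/SSC-high; debris CD45-negative.
POPULATION_PARAMS = {
    "lymphocyte": {"fsc": (450.0, 80.0), "ssc": (120.0, 30.0), "cd45_mu": 3.0, "cd45_sd": 0.10},
    "monocyte": {"fsc": (600.0, 90.0), "ssc": (420.0, 60.0), "cd45_mu": 2.9, "cd45_sd": 0.10},
    "granulocyte": {"fsc": (620.0, 90.0), "ssc": (650.0, 80.0), "cd45_mu": 2.3, "cd45_sd": 0.12},
    "debris": {"fsc": (60.0, 25.0), "ssc": (40.0, 20.0), "cd45_mu": 0.3, "cd45_sd": 0.25},
}

#: log10-scale isotype (non-specific binding) location and spread; the
#: negative component of every marker mixture, centred in the first decade.
ISOTYPE_MU = 0.4
ISOTYPE_SIGMA = 0.12

#: log10 spread of positive populations (tighter for weak sIgM so the
#: positive peak stays inside its decade and clear of the isotype cut).
POSITIVE_SIGMA = 0.12
WEAK_SIGMA = 0.06

#: Positive-population median intensity per sIgM pattern (linear units).
SIGM_PATTERN_MFI = {"weak": 8.8, "moderate": 40.0, "strong": 320.0}

#: Minimum expected B-cell yield before a sample is flagged low-yield.
MIN_B_CELLS = 100


class ConfigurationError(ValueError):
    """Raised for invalid templates or cohort configuration."""


# ---------------------------------------------------------------------------
# bounded distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointMass:
    """Degenerate distribution concentrated at a single value."""

    value: float

    def support(self) -> tuple[float, float]:
        return (self.value, self.value)

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.value)


@dataclass(frozen=True)
class ScaledBeta:
    """Beta distribution rescaled to [lo, hi] with its mode at ``peak``.

    ``concentration`` controls the spread; the resulting median tracks
    ``peak`` closely for moderate concentrations, which is how template
    medians are matched to the published per-subtype summaries.
    """

    lo: float
    hi: float
    peak: float
    concentration: float = 8.0

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise ConfigurationError(f"empty support [{self.lo}, {self.hi}]")
        if not (self.lo <= self.peak <= self.hi):
            raise ConfigurationError(f"peak {self.peak} outside [{self.lo}, {self.hi}]")
        if self.concentration <= 0:
            raise ConfigurationError("concentration must be positive")

    def support(self) -> tuple[float, float]:
        return (self.lo, self.hi)

    def sample(self, rng: np.random.Generator) -> float:
        m = (self.peak - self.lo) / (self.hi - self.lo)
        a = 1.0 + self.concentration * m
        b = 1.0 + self.concentration * (1.0 - m)
        return float(self.lo + (self.hi - self.lo) * rng.beta(a, b))


@dataclass(frozen=True)
class LogJitter:
    """Positive value with multiplicative log10-normal jitter around a median."""

    median: float
    log10_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ConfigurationError("median must be positive")

    def support(self) -> tuple[float, float]:
        return (0.0, math.inf)

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.median * 10.0 ** rng.normal(0.0, self.log10_sd))


# ---------------------------------------------------------------------------
# templates and profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosisTemplate:
    """Generative template for one patient case.

    ``positivity`` maps each panel marker to a bounded distribution on
    [0, 100] (percent of B cells positive); ``intensity`` maps markers to
    positive-population MFI distributions (CD200 intensity is instead derived
    from ``cd200_mfir`` so the measured MFI ratio lands on target; sIgM
    intensity is derived from ``sigm_pattern``).
    """

    diagnosis_label: str
    positivity: Mapping[str, object]
    intensity: Mapping[str, object]
    cd200_mfir: object
    sigm_pattern: str
    mixture_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(MIXTURE_WEIGHTS)
    )
    b_cell_fraction: float = 0.90

    def __post_init__(self) -> None:
        if self.diagnosis_label not in DIAGNOSES:
            raise ConfigurationError(f"unknown diagnosis {self.diagnosis_label!r}")
        total = sum(self.mixture_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"mixture weights sum to {total}, not 1")
        if not (0.0 < self.b_cell_fraction <= 1.0):
            raise ConfigurationError("b_cell_fraction must be in (0, 1]")
        if self.sigm_pattern not in SIGM_PATTERN_MFI:
            raise ConfigurationError(f"unknown sIgM pattern {self.sigm_pattern!r}")
        for marker in PANEL_MARKERS:
            if marker not in self.positivity:
                raise ConfigurationError(f"no positivity distribution for {marker}")
            lo, hi = self.positivity[marker].support()
            if lo < 0.0 or hi > 100.0:
                raise ConfigurationError(
                    f"{marker} positivity support [{lo}, {hi}] outside [0, 100]"
                )
        cd200_lo, cd200_hi = self.positivity["CD200"].support()
        if self.diagnosis_label in CLL_LABELS:
            if cd200_lo < 50.6:
                raise ConfigurationError("CLL template CD200 support must be >= 50.6")
            cd5_lo, _ = self.positivity["CD5"].support()
            if cd5_lo < 30.0:
                raise ConfigurationError("CLL template CD5 support must be >= 30")
        if self.diagnosis_label == "MCL" and cd200_hi >= 30.0:
            raise ConfigurationError("MCL template CD200 support must stay below 30")


@dataclass(frozen=True)
class MarkerProfile:
    """Sampled generative targets for a single patient."""

    sample_id: str
    diagnosis_label: str
    percent_positive: Mapping[str, float]
    positive_mfi: Mapping[str, float]
    sigm_pattern: str
    cd200_mfir_target: float
    isotype_mu: float = ISOTYPE_MU
    isotype_sigma: float = ISOTYPE_SIGMA
    mixture_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(MIXTURE_WEIGHTS)
    )
    b_cell_fraction: float = 0.90

    @property
    def isotype_mean(self) -> float:
        """Arithmetic mean of the log-normal isotype distribution."""
        return isotype_mean(self.isotype_mu, self.isotype_sigma)


def isotype_mean(mu: float, sigma: float) -> float:
    """Arithmetic mean of 10**N(mu, sigma)."""
    return 10.0 ** mu * math.exp(0.5 * (sigma * LN10) ** 2)


def sample_patient_profile(
    template: DiagnosisTemplate,
    rng: np.random.Generator,
    sample_id: str = "",
) -> MarkerProfile:
    """Draw one patient's marker targets from a diagnosis template.

    CD200 positive-population intensity is solved from the drawn target MFIR
    so that the pipeline-measured ratio (over all B cells, against the
    isotype mean) recovers the target; sIgM intensity is placed by its
    pattern's log decade.
    """
    iso_mu = ISOTYPE_MU + float(rng.normal(0.0, 0.01))
    iso_mean = isotype_mean(iso_mu, ISOTYPE_SIGMA)

    percent = {m: float(template.positivity[m].sample(rng)) for m in PANEL_MARKERS}
    mfir_target = float(template.cd200_mfir.sample(rng))
    if mfir_target < 0:
        raise ConfigurationError("CD200 MFIR target must be >= 0")

    mfi: dict[str, float] = {}
    for marker in PANEL_MARKERS:
        if marker == "CD200":
            frac = percent["CD200"] / 100.0
            if frac <= 0.0:
                mfi[marker] = iso_mean
            else:
                target = iso_mean * (mfir_target - (1.0 - frac)) / frac
                mfi[marker] = float(np.clip(target, 10.0, 8000.0))
        elif marker == "sIgM":
            base = SIGM_PATTERN_MFI[template.sigm_pattern]
            mfi[marker] = float(base * 10.0 ** rng.uniform(-0.02, 0.02))
        else:
            mfi[marker] = float(template.intensity[marker].sample(rng))

    return MarkerProfile(
        sample_id=sample_id,
        diagnosis_label=template.diagnosis_label,
        percent_positive=percent,
        positive_mfi=mfi,
        sigm_pattern=template.sigm_pattern,
        cd200_mfir_target=mfir_target,
        isotype_mu=iso_mu,
        mixture_weights=dict(template.mixture_weights),
        b_cell_fraction=template.b_cell_fraction,
    )


# ---------------------------------------------------------------------------
# event generation
# ---------------------------------------------------------------------------

@dataclass
class EventBundle:
    """One simulated sample: stained tube, isotype tube, hidden truth labels.

    Truth labels live outside the event columns so no downstream computation
    can consume them; they exist only for validation.
    """

    stained: pd.DataFrame
    isotype: pd.DataFrame
    truth_stained: pd.DataFrame
    truth_isotype: pd.DataFrame
    low_yield: bool = False


def _population_counts(
    n_events: int, weights: Mapping[str, float], rng: np.random.Generator
) -> dict[str, int]:
    names = list(POPULATION_PARAMS)
    p = np.array([weights[n] for n in names], dtype=float)
    counts = rng.multinomial(n_events, p / p.sum())
    return dict(zip(names, (int(c) for c in counts)))


def _scatter_block(pop: str, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    par = POPULATION_PARAMS[pop]
    fsc = np.maximum(rng.normal(*par["fsc"], size=n), 0.0)
    ssc = np.maximum(rng.normal(*par["ssc"], size=n), 0.0)
    cd45 = 10.0 ** rng.normal(par["cd45_mu"], par["cd45_sd"], size=n)
    return {"FSC": fsc, "SSC": ssc, "CD45": cd45}


def _isotype_draw(n: int, mu: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    return 10.0 ** rng.normal(mu, sigma, size=n)


def _positive_draw(n: int, target_mean: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    # place the log-normal so its arithmetic mean equals target_mean
    mu = math.log10(target_mean) - 0.5 * sigma * sigma * LN10
    return 10.0 ** rng.normal(mu, sigma, size=n)


def generate_events(
    profile: MarkerProfile,
    n_events: int,
    rng: np.random.Generator,
) -> EventBundle:
    """Simulate one stained tube and its matched isotype-control tube.

    Stained B-cell marker values are a two-component mixture: a negative
    component distributed as the isotype control and a positive component
    at the profile's positive MFI, with positive fraction equal to the
    profile's target percent-positive. Non-B populations are placed so the
    CD45/SSC lymphocyte gate separates them.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")

    expected_b = (
        n_events * profile.mixture_weights["lymphocyte"] * profile.b_cell_fraction
    )
    low_yield = expected_b < MIN_B_CELLS
    if low_yield:
        warnings.warn(
            f"sample {profile.sample_id or '<unnamed>'}: expected B-cell yield "
            f"{expected_b:.0f} < {MIN_B_CELLS}",
            stacklevel=2,
        )

    tubes = {}
    truths = {}
    for tube in ("stained", "isotype"):
        counts = _population_counts(n_events, profile.mixture_weights, rng)
        n_lym = counts["lymphocyte"]
        n_b = int(rng.binomial(n_lym, profile.b_cell_fraction)) if tube == "stained" else 0
        if tube == "isotype":
            # isotype tube carries the same cells; B-cell split is irrelevant
            # because every panel marker is stained with the control antibody
            n_b = int(rng.binomial(n_lym, profile.b_cell_fraction))

        cols = {c: [] for c in EVENT_COLUMNS}
        pop_label = []
        is_b = []
        for pop in POPULATION_PARAMS:
            n = counts[pop]
            block = _scatter_block(pop, n, rng)
            for c in GATING_COLUMNS:
                cols[c].append(block[c])
            if pop == "lymphocyte":
                b_mask = np.zeros(n, dtype=bool)
                b_mask[:n_b] = True
            else:
                b_mask = np.zeros(n, dtype=bool)
            pop_label.append(np.full(n, pop))
            is_b.append(b_mask)

            for marker in PANEL_MARKERS:
                if pop == "debris":
                    vals = 10.0 ** rng.normal(0.1, 0.20, size=n)
                elif tube == "isotype" or pop != "lymphocyte":
                    vals = _isotype_draw(n, profile.isotype_mu, profile.isotype_sigma, rng)
                else:
                    vals = _isotype_draw(n, profile.isotype_mu, profile.isotype_sigma, rng)
                    nb = int(b_mask.sum())
                    if nb:
                        frac = profile.percent_positive[marker] / 100.0
                        pos = rng.random(nb) < frac
                        npos = int(pos.sum())
                        if npos:
                            sigma = (
                                WEAK_SIGMA
                                if marker == "sIgM" and profile.sigm_pattern == "weak"
                                else POSITIVE_SIGMA
                            )
                            bvals = vals[:nb]
                            bvals[pos] = _positive_draw(
                                npos, profile.positive_mfi[marker], sigma, rng
                            )
                            vals[:nb] = bvals
                cols[marker].append(vals)

        frame = pd.DataFrame(
            {c: np.concatenate(cols[c]) for c in EVENT_COLUMNS}
        )
        truth = pd.DataFrame(
            {
                "population": np.concatenate(pop_label),
                "is_b_cell": np.concatenate(is_b),
            }
        )
        tubes[tube] = frame
        truths[tube] = truth

    return EventBundle(
        stained=tubes["stained"],
        isotype=tubes["isotype"],
        truth_stained=truths["stained"],
        truth_isotype=truths["isotype"],
        low_yield=low_yield,
    )


# ---------------------------------------------------------------------------
# per-diagnosis case designs
# ---------------------------------------------------------------------------

# percent-positive distributions for markers designed positive / negative;
# every support edge sits >= 5 points from the 30% decision boundary
_POS_PCT = {
    # B cells are CD19+ by definition; near-total positivity keeps the
    # CD19-gated percent consistent with the generative target
    "CD19": ScaledBeta(98.0, 100.0, 99.5),
    "CD20": ScaledBeta(80.0, 100.0, 95.0),
    "CD5": ScaledBeta(65.0, 99.0, 90.0),
    "CD23": ScaledBeta(40.0, 99.0, 80.0),
    "FMC7": ScaledBeta(35.0, 95.0, 60.0),
    "CD79b": ScaledBeta(35.0, 95.0, 65.0),
    "CD10": ScaledBeta(40.0, 90.0, 65.0),
    "sIgM": ScaledBeta(80.0, 98.0, 92.0),
}
_NEG_PCT = ScaledBeta(0.5, 24.0, 8.0)

# CD200 percent-positive by diagnosis and designed status, matched to the
# published per-subtype medians/ranges (positive side) or capped at 25 to
# keep negative cases clear of the 30% boundary
_CD200_PCT = {
    ("CLL-typical", True): ScaledBeta(88.9, 100.0, 98.0),
    ("CLL-atypical", True): ScaledBeta(50.6, 84.7, 62.6),
    ("MCL", False): ScaledBeta(0.1, 25.0, 2.3),
    ("MZL", True): ScaledBeta(35.0, 88.0, 62.0),
    ("MZL", False): ScaledBeta(0.4, 25.0, 5.0),
    ("HCL", True): ScaledBeta(35.0, 91.8, 60.0),
    ("HCL", False): ScaledBeta(0.9, 25.0, 5.0),
    ("FL", True): ScaledBeta(35.0, 70.6, 55.0),
    ("FL", False): ScaledBeta(0.9, 25.0, 1.7),
    ("OTHER", True): ScaledBeta(35.0, 57.6, 48.0),
    ("OTHER", False): ScaledBeta(1.9, 25.0, 5.9),
}

# CD200 target MFIR: positive cases >= 25 (comfortably above the 18 cut),
# negative cases <= 12 (comfortably below), per-subtype medians from the
# published summary where available
_CD200_MFIR = {
    ("CLL-typical", True): ScaledBeta(39.3, 69.9, 59.8),
    ("CLL-atypical", True): ScaledBeta(40.0, 57.0, 50.3),
    ("MZL", True): ScaledBeta(25.0, 58.0, 35.0),
    ("HCL", True): ScaledBeta(25.0, 77.0, 46.5),
    ("FL", True): ScaledBeta(25.0, 43.0, 30.0),
    ("OTHER", True): ScaledBeta(25.0, 45.0, 30.0),
}
_CD200_MFIR_NEG = ScaledBeta(0.7, 12.0, 3.3)

_POS_MFI = {
    "CD19": LogJitter(250.0),
    "CD20": LogJitter(400.0),
    "CD5": LogJitter(150.0),
    "CD23": LogJitter(80.0),
    "FMC7": LogJitter(120.0),
    "CD79b": LogJitter(100.0),
    "CD10": LogJitter(100.0),
}

_B_CELL_FRACTION = {
    "CLL-typical": 0.90,
    "CLL-atypical": 0.90,
    "MCL": 0.85,
    "MZL": 0.80,
    "HCL": 0.75,
    "FL": 0.80,
    "OTHER": 0.80,
}


def make_case_template(
    diagnosis: str,
    positive_markers: frozenset[str] | set[str],
    sigm_pattern: str,
    cd200_positive: bool,
) -> DiagnosisTemplate:
    """Build the template for one designed case.

    ``positive_markers`` are the panel markers (other than CD19/CD20/CD200)
    whose percent-positive target is drawn above the 30% cut; everything
    else draws from the negative distribution.
    """
    positivity: dict[str, object] = {}
    for marker in PANEL_MARKERS:
        if marker == "CD200":
            positivity[marker] = _CD200_PCT[(diagnosis, cd200_positive)]
        elif marker == "sIgM":
            positivity[marker] = _POS_PCT["sIgM"]
        elif marker in ("CD19", "CD20") or marker in positive_markers:
            positivity[marker] = _POS_PCT[marker]
        else:
            positivity[marker] = _NEG_PCT
    mfir = (
        _CD200_MFIR[(diagnosis, True)] if cd200_positive else _CD200_MFIR_NEG
    )
    return DiagnosisTemplate(
        diagnosis_label=diagnosis,
        positivity=positivity,
        intensity=dict(_POS_MFI),
        cd200_mfir=mfir,
        sigm_pattern=sigm_pattern,
        b_cell_fraction=_B_CELL_FRACTION[diagnosis],
    )


def _designs(
    diagnosis: str, *rows: tuple[int, set[str], str, bool]
) -> list[DiagnosisTemplate]:
    out: list[DiagnosisTemplate] = []
    for count, pos, sigm, cd200 in rows:
        tpl = make_case_template(diagnosis, pos, sigm, cd200)
        out.extend([tpl] * count)
    return out


def default_case_designs() -> dict[str, list[DiagnosisTemplate]]:
    """Fixed per-diagnosis case designs for the default 252-case cohort.

    The classical-score histogram of each diagnosis matches the published
    per-subtype score column; CD200-positive counts per subtype are 199 CLL,
    5 HCL, 12 MZL, 1 FL, 2 other (PLL-like) and 0 MCL; exactly one non-CLL
    case (the HCL scoring 3) gains the CD200 point into score 4.
    """
    return {
        # 94 score-5; 95 score-4 missing one point (45 FMC7+, 45 CD79b+,
        # 3 CD23-, 2 sIgM-moderate)
        "CLL-typical": _designs(
            "CLL-typical",
            (94, {"CD5", "CD23"}, "weak", True),
            (45, {"CD5", "CD23", "FMC7"}, "weak", True),
            (45, {"CD5", "CD23", "CD79b"}, "weak", True),
            (3, {"CD5"}, "weak", True),
            (2, {"CD5", "CD23"}, "moderate", True),
        ),
        # all score 3 (missing two classical points), all CD200-positive
        "CLL-atypical": _designs(
            "CLL-atypical",
            (4, {"CD5", "FMC7"}, "weak", True),
            (3, {"CD5", "CD23", "FMC7", "CD79b"}, "weak", True),
            (3, {"CD5", "CD23", "FMC7"}, "moderate", True),
        ),
        # CD5+ CD23- CD200-; scores 1(10), 2(7), 3(3)
        "MCL": _designs(
            "MCL",
            (10, {"CD5", "FMC7", "CD79b"}, "strong", False),
            (7, {"CD5", "FMC7", "CD79b"}, "weak", False),
            (2, {"CD5", "CD79b"}, "weak", False),
            (1, {"CD5"}, "strong", False),
        ),
        # scores 0(7), 1(4), 2(4), 3(2); 12/17 CD200-positive
        "MZL": _designs(
            "MZL",
            (7, {"FMC7", "CD79b"}, "moderate", True),
            (1, {"CD23", "FMC7", "CD79b"}, "moderate", True),
            (3, {"CD23", "FMC7", "CD79b"}, "moderate", False),
            (2, {"CD23", "FMC7", "CD79b"}, "weak", True),
            (2, {"CD23", "CD79b"}, "moderate", True),
            (2, {"CD23", "CD79b"}, "weak", False),
        ),
        # scores 0(1), 1(3), 2(3), 3(1); 5/8 CD200-positive; the score-3
        # case is the single non-CLL that reaches augmented score 4
        "HCL": _designs(
            "HCL",
            (1, {"FMC7", "CD79b"}, "moderate", False),
            (2, {"CD79b"}, "moderate", True),
            (1, {"FMC7", "CD79b"}, "weak", False),
            (2, set(), "moderate", True),
            (1, set(), "moderate", False),
            (1, set(), "weak", True),
        ),
        # scores 2(2), 3(1); 1/3 CD200-positive; CD10+ follicular phenotype
        "FL": _designs(
            "FL",
            (1, {"CD23", "CD79b", "CD10"}, "moderate", True),
            (1, {"CD23", "CD79b", "CD10"}, "moderate", False),
            (1, {"CD23", "CD10"}, "moderate", False),
        ),
        # 2 LPL-like (scores 0, 1), 1 WM-like (score 2), 2 PLL-like
        # (score 2, CD200-positive, four-marker score 3)
        "OTHER": _designs(
            "OTHER",
            (1, {"FMC7", "CD79b"}, "strong", False),
            (1, {"FMC7", "CD79b"}, "weak", False),
            (1, {"CD23", "CD79b"}, "strong", False),
            (2, {"CD5", "FMC7", "CD79b"}, "weak", True),
        ),
    }


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: Default cohort composition (the study cohort being emulated).
DEFAULT_COMPOSITION = {
    "CLL-typical": 189,
    "CLL-atypical": 10,
    "MCL": 20,
    "MZL": 17,
    "HCL": 8,
    "FL": 3,
    "OTHER": 5,
}

#: Bone-marrow specimens out of the full cohort (remainder peripheral blood).
N_BONE_MARROW = 57


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort run."""

    composition: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    events_per_sample: int = DEFAULT_EVENTS_PER_SAMPLE
    outdir: Path | None = None

    def __post_init__(self) -> None:
        for diag, count in self.composition.items():
            if diag not in DIAGNOSES:
                raise ConfigurationError(f"unknown diagnosis {diag!r}")
            if count < 0:
                raise ConfigurationError(f"negative count for {diag}")
        if self.events_per_sample < 1:
            raise ConfigurationError("events_per_sample must be >= 1")


@dataclass
class SimulatedSample:
    """One in-memory cohort member."""

    sample_id: str
    diagnosis_label: str
    specimen_type: str
    seed_offset: int
    profile: MarkerProfile
    events: EventBundle


def _case_plan(config: CohortConfig) -> list[tuple[str, DiagnosisTemplate]]:
    designs = default_case_designs()
    plan: list[tuple[str, DiagnosisTemplate]] = []
    for diag in DIAGNOSES:
        count = int(config.composition.get(diag, 0))
        if count == 0:
            continue
        cases = designs[diag]
        for i in range(count):
            plan.append((diag, cases[i % len(cases)]))
    return plan


def _specimen_types(n: int) -> list[str]:
    """Deterministic PB/BM assignment at the cohort's BM proportion."""
    total = sum(DEFAULT_COMPOSITION.values())
    out = []
    for i in range(n):
        bm = ((i + 1) * N_BONE_MARROW) // total - (i * N_BONE_MARROW) // total
        out.append("BM" if bm else "PB")
    return out


def sample_rng(master_seed: int, sample_index: int) -> np.random.Generator:
    """Independent per-sample stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(sample_index)]))


def iter_cohort(config: CohortConfig, master_seed: int) -> Iterator[SimulatedSample]:
    """Generate the cohort sample by sample, fully in memory.

    Each sample uses an independent stream derived from (master_seed,
    sample_index), so any single sample is regenerable in isolation.
    """
    plan = _case_plan(config)
    specimens = _specimen_types(len(plan))
    for idx, (diag, template) in enumerate(plan):
        rng = sample_rng(master_seed, idx)
        sid = f"S{idx:03d}"
        profile = sample_patient_profile(template, rng, sample_id=sid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = generate_events(profile, config.events_per_sample, rng)
        yield SimulatedSample(
            sample_id=sid,
            diagnosis_label=diag,
            specimen_type=specimens[idx],
            seed_offset=idx,
            profile=profile,
            events=bundle,
        )


def generate_cohort(config: CohortConfig, master_seed: int) -> pd.DataFrame:
    """Write the cohort to disk and return the manifest.

    Writes per sample: ``<id>.events.csv``, ``<id>.isotype.csv`` and the
    ground-truth side file ``<id>.truth.csv`` (never consumed downstream),
    plus ``manifest.csv`` in the output directory.
    """
    if config.outdir is None:
        raise ConfigurationError("generate_cohort requires config.outdir")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for sample in iter_cohort(config, master_seed):
        events_path = outdir / f"{sample.sample_id}.events.csv"
        isotype_path = outdir / f"{sample.sample_id}.isotype.csv"
        truth_path = outdir / f"{sample.sample_id}.truth.csv"
        sample.events.stained.to_csv(events_path, index=False, float_format="%.3f")
        sample.events.isotype.to_csv(isotype_path, index=False, float_format="%.3f")
        truth = pd.concat(
            [
                sample.events.truth_stained.assign(tube="stained"),
                sample.events.truth_isotype.assign(tube="isotype"),
            ],
            ignore_index=True,
        )
        truth.to_csv(truth_path, index=False)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "diagnosis_label": sample.diagnosis_label,
                "specimen_type": sample.specimen_type,
                "events_path": str(events_path),
                "isotype_path": str(isotype_path),
                "seed_offset": sample.seed_offset,
                "low_yield_warning": sample.events.low_yield,
            }
        )

    manifest = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "diagnosis_label",
            "specimen_type",
            "events_path",
            "isotype_path",
            "seed_offset",
            "low_yield_warning",
        ],
    )
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
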