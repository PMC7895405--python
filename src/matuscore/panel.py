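"""Panel and column conventions shared by every stage of the pipeline.

Event tables are one row per cell on a linear fluorescence scale spanning
four decades [1, 1e4]. Scatter channels (FSC, SSC) and CD45 are used for
gating only; the remaining columns are the antibody panel quantified per
sample.
"""

#: Columns of every events/isotype CSV, in file order.
EVENT_COLUMNS = (
    "FSC", "SSC", "CD45",
    "CD19", "CD20", "CD5", "CD23", "FMC7", "CD79b", "CD200", "sIgM", "CD10",
)

#: Scatter/gating channels; never scored.
GATING_COLUMNS = ("FSC", "SSC", "CD45")

#: Antibody panel quantified on gated B cells.
PANEL_MARKERS = tuple(c for c in EVENT_COLUMNS if c not in GATING_COLUMNS)

#: Markers entering the classical 5-marker score.
CLASSICAL_MARKERS = ("CD5", "CD23", "FMC7", "CD79b", "sIgM")

#: Markers entering the simplified 4-marker score.
FOUR_MARKER_MARKERS = ("CD5", "CD23", "sIgM", "CD200")

#: Percent-positive cutoff used by every score point rule.
POSITIVITY_CUTOFF = 30.0

#: MFIR cutoff for the optional CD200-by-MFIR scoring mode.
MFIR_CUTOFF = 18.0

#: Intensity pattern classes on the 4-decade log scale.
PATTERNS = ("weak", "moderate", "strong")

#: Diagnosis labels used throughout; CLL split into its two phenotypes.
DIAGNOSES = ("CLL-typical", "CLL-atypical", "MCL", "MZL", "HCL", "FL", "OTHER")

#: Labels counted as CLL by the binary diagnostic screen.
CLL_LABELS = ("CLL-typical", "CLL-atypical")


def is_cll(diagnosis_label: str) -> bool:
    """True if the label belongs to the CLL group (typical or atypical)."""
    return diagnosis_label in CLL_LABELS
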