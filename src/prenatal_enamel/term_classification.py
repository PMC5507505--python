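"""Pre-term vs full-term classification from prenatal crown formation time.

The gestational arithmetic: deciduous central incisor crowns start
mineralizing between gestational weeks 13 and 20 (days 91-140).  Taking a
singleton pregnancy as 39 weeks (273 days), the prenatal crown formation
time (pCFT) of a full-term birth must fall between 273-140 = 133 and
273-91 = 182 days.  Any pCFT below the full-term lower bound therefore
indicates a pre-term birth; a more conservative operational threshold
(120 days by default, motivated by a gap in the empirical pCFT
distribution) classifies as pre-term every individual with pCFT <= the
threshold (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cft_estimators import PcftEstimate
from .enamel_data import Finding

__all__ = [
    "GestationModel",
    "TermLabel",
    "ConcordanceTable",
    "ThresholdSuggestion",
    "CohortClassification",
    "full_term_pcft_bounds",
    "classify_term",
    "classify_cohort",
    "concordance",
    "suggest_threshold",
]

PRETERM = "pre-term"
FULLTERM = "full-term"
TermLabel = str


@dataclass(frozen=True)
class GestationModel:
    """Gestational constants (days)."""

    gestation_days: float = 273.0
    initiation_min_days: float = 91.0
    initiation_max_days: float = 140.0
    preterm_threshold_days: float = 120.0

    def __post_init__(self) -> None:
        if not (0 < self.initiation_min_days < self.initiation_max_days < self.gestation_days):
            raise ValueError(
                "require 0 < initiation_min < initiation_max < gestation_days, got "
                f"({self.initiation_min_days}, {self.initiation_max_days}, {self.gestation_days})"
            )


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 agreement between two pCFT-based term diagnoses."""

    n_both_preterm: int
    n_both_fullterm: int
    n_direct_only_preterm: int
    n_predicted_only_preterm: int
    discordant_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return (
            self.n_both_preterm
            + self.n_both_fullterm
            + self.n_direct_only_preterm
            + self.n_predicted_only_preterm
        )

    @property
    def n_discordant(self) -> int:
        return self.n_direct_only_preterm + self.n_predicted_only_preterm


@dataclass(frozen=True)
class ThresholdSuggestion:
    """Advisory threshold from the widest gap in the pCFT distribution."""

    days: float
    gap_days: float
    findings: tuple[Finding, ...] = ()


@dataclass
class CohortClassification:
    labels: dict[str, TermLabel]
    n_preterm: int
    n_fullterm: int
    survived_preterm_ids: list[str] = field(default_factory=list)


def full_term_pcft_bounds(model: GestationModel | None = None) -> tuple[float, float]:
    """(min, max) pCFT compatible with a full-term birth.

    Latest initiation gives the least prenatal enamel:
    min = gestation - initiation_max; max = gestation - initiation_min.
    """
    model = model or GestationModel()
    return (
        model.gestation_days - model.initiation_max_days,
        model.gestation_days - model.initiation_min_days,
    )


def classify_term(pcft_days: float, model: GestationModel | None = None) -> TermLabel:
    """Pre-term iff pCFT <= threshold (inclusive); values compared unrounded."""
    model = model or GestationModel()
    if not pcft_days > 0:
        raise ValueError(f"pCFT must be positive, got {pcft_days}")
    return PRETERM if pcft_days <= model.preterm_threshold_days else FULLTERM


def classify_cohort(
    estimates: list[PcftEstimate],
    model: GestationModel | None = None,
    nl_by_id: "dict[str, bool] | None" = None,
) -> CohortClassification:
    """Classify every individual and count the pre-term/full-term split.

    If an id -> NL-presence mapping is supplied, pre-term individuals who
    nonetheless formed a neonatal line (i.e. survived birth by ~10+ days)
    are flagged — pre-term birth and perinatal death are distinct events.
    """
    if not estimates:
        raise ValueError("empty cohort")
    model = model or GestationModel()
    labels = {e.tooth_id: classify_term(e.days, model) for e in estimates}
    n_pre = sum(1 for v in labels.values() if v == PRETERM)
    survived = []
    if nl_by_id:
        survived = [tid for tid, lab in labels.items() if lab == PRETERM and nl_by_id.get(tid)]
    return CohortClassification(
        labels=labels,
        n_preterm=n_pre,
        n_fullterm=len(labels) - n_pre,
        survived_preterm_ids=sorted(survived),
    )


def concordance(
    direct_labels: list[TermLabel],
    predicted_labels: list[TermLabel],
    ids: "list[str] | None" = None,
) -> ConcordanceTable:
    """2x2 agreement table between aligned diagnosis lists."""
    if len(direct_labels) != len(predicted_labels):
        raise ValueError(
            f"label lists must align, got {len(direct_labels)} and {len(predicted_labels)}"
        )
    if ids is None:
        ids = [str(i) for i in range(len(direct_labels))]
    both_pre = both_full = d_only = p_only = 0
    discordant = []
    for tid, d, p in zip(ids, direct_labels, predicted_labels):
        if d == PRETERM and p == PRETERM:
            both_pre += 1
        elif d != PRETERM and p != PRETERM:
            both_full += 1
        elif d == PRETERM:
            d_only += 1
            discordant.append(tid)
        else:
            p_only += 1
            discordant.append(tid)
    return ConcordanceTable(both_pre, both_full, d_only, p_only, tuple(discordant))


def suggest_threshold(
    pcft_values: "list[float] | np.ndarray",
    model: GestationModel | None = None,
    window: "tuple[float, float] | None" = None,
) -> ThresholdSuggestion:
    """Data-driven threshold: lower edge of the widest gap between
    consecutive sorted pCFT values inside the search window.

    The window defaults to [100, derived full-term minimum].  Ties go to
    the first (lowest) maximal gap.  Advisory only: the configured
    threshold is never silently replaced, and if fewer than two values
    fall in the window the configured default is returned with a finding.
    """
    model = model or GestationModel()
    values = np.asarray(pcft_values, dtype=float)
    if values.size < 5:
        raise ValueError(f"need at least 5 values, got {values.size}")
    if window is None:
        window = (100.0, full_term_pcft_bounds(model)[0])
    lo, hi = window
    inside = np.sort(values[(values >= lo) & (values <= hi)])
    if inside.size < 2:
        return ThresholdSuggestion(
            days=model.preterm_threshold_days,
            gap_days=0.0,
            findings=(
                Finding(
                    "warning",
                    "suggest_threshold",
                    f"fewer than 2 pCFT values in window [{lo}, {hi}]; "
                    "returning the configured threshold",
                ),
            ),
        )
    gaps = np.diff(inside)
    i = int(np.argmax(gaps))  # argmax returns the FIRST maximal gap
    return ThresholdSuggestion(days=float(inside[i]), gap_days=float(gaps[i]))
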