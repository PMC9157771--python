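"""Dose-adaptation classification against the 8–45 mg/L meropenem window.

The therapeutic window corresponds to 100% ƒT > 4×MIC for a MIC of 2 mg/L
(lower bound 8 mg/L) with 45 mg/L as the toxicity ceiling. A measured or
predicted concentration maps to a recommendation: below the window → increase
the dose, inside (bounds inclusive) → maintain, above → decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TARGET_LOW",
    "TARGET_HIGH",
    "DoseRecommendation",
    "AdaptationTable",
    "classify",
    "adaptation_accuracy",
]

TARGET_LOW = 8.0  # mg/L, 4×MIC for MIC 2 mg/L
TARGET_HIGH = 45.0  # mg/L, toxicity ceiling

CATEGORIES = ("increase", "maintain", "decrease")


@dataclass(frozen=True)
class DoseRecommendation:
    category: str
    concentration: float
    target_low: float = TARGET_LOW
    target_high: float = TARGET_HIGH


def classify(conc: float, low: float = TARGET_LOW, high: float = TARGET_HIGH
             ) -> DoseRecommendation:
    """Recommend a dose direction for a concentration (bounds inclusive)."""
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    if not low < high:
        raise ValueError("target bounds must satisfy low < high")
    if conc < low:
        cat = "increase"
    elif conc <= high:
        cat = "maintain"
    else:
        cat = "decrease"
    return DoseRecommendation(cat, float(conc), low, high)


@dataclass
class AdaptationTable:
    """Per-category agreement between predicted and observed recommendations."""

    correct: dict[str, int] = field(default_factory=dict)
    incorrect: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return sum(self.correct.values()) + sum(self.incorrect.values())

    @property
    def accuracy(self) -> float:
        """Percentage of concentrations whose dose direction was predicted."""
        if self.n == 0:
            raise ValueError("empty adaptation table")
        return 100.0 * sum(self.correct.values()) / self.n

    @classmethod
    def from_counts(cls, correct_by_cat, total_by_cat) -> "AdaptationTable":
        """Build from per-observed-category counts (in increase/maintain/decrease
        order), e.g. a published contingency row."""
        correct = dict(zip(CATEGORIES, correct_by_cat))
        incorrect = {
            c: t - k for c, k, t in zip(CATEGORIES, correct_by_cat, total_by_cat)
        }
        if any(v < 0 for v in incorrect.values()):
            raise ValueError("correct counts exceed category totals")
        return cls(correct=correct, incorrect=incorrect)

    def as_dict(self) -> dict:
        return {
            "correct": dict(self.correct),
            "incorrect": dict(self.incorrect),
            "n": self.n,
            "accuracy": self.accuracy,
        }


def adaptation_accuracy(predicted_conc, observed_conc,
                        low: float = TARGET_LOW, high: float = TARGET_HIGH
                        ) -> AdaptationTable:
    """Score predicted against observed dose-adaptation directions."""
    pred = np.asarray(list(predicted_conc), dtype=float)
    obs = np.asarray(list(observed_conc), dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("predicted and observed lists must be equal-length, non-empty")
    table = AdaptationTable(
        correct={c: 0 for c in CATEGORIES}, incorrect={c: 0 for c in CATEGORIES}
    )
    for p, o in zip(pred, obs):
        pc = classify(p, low, high).category
        oc = classify(o, low, high).category
        if pc == oc:
            table.correct[oc] += 1
        else:
            table.incorrect[oc] += 1
    return table
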