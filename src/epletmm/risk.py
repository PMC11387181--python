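"""Threshold-based alloimmune risk categorization.

A :class:`CategoryScheme` partitions the (dr_max, dq_max) plane into
LOW / INTERMEDIATE / HIGH.  LOW requires both maxima strictly below the
low cutoffs; HIGH is either a DQ-only rule (dq >= t) or a conjunction
(dr >= t1 AND dq >= t2); everything else is INTERMEDIATE.  Schemes are
data, so cohort-specific rule sets can be supplied via configuration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ContractError, ValidationError


class RiskCategory(enum.IntEnum):
    LOW = 0
    INTERMEDIATE = 1
    HIGH = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class CategoryScheme:
    """Low cutoffs plus a high rule.

    ``high_dr_ge is None`` means the high rule is DQ-only
    (``dq_max >= high_dq_ge``); otherwise it is the conjunction
    ``dr_max >= high_dr_ge AND dq_max >= high_dq_ge``.
    """

    name: str
    dr_low_lt: int
    dq_low_lt: int
    high_dq_ge: int
    high_dr_ge: int | None = None

    def __post_init__(self):
        if min(self.dr_low_lt, self.dq_low_lt, self.high_dq_ge) < 0:
            raise ValidationError("scheme thresholds must be non-negative")
        # low and high regions must be disjoint
        overlap = self.high_dq_ge < self.dq_low_lt and (
            self.high_dr_ge is None or self.high_dr_ge < self.dr_low_lt
        )
        if overlap:
            raise ValidationError(
                f"scheme {self.name!r}: low and high regions overlap"
            )

    def high_rule(self, dr_max: int, dq_max: int) -> bool:
        if self.high_dr_ge is None:
            return dq_max >= self.high_dq_ge
        return dr_max >= self.high_dr_ge and dq_max >= self.high_dq_ge

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "dr_low_lt": self.dr_low_lt,
            "dq_low_lt": self.dq_low_lt,
            "high_dq_ge": self.high_dq_ge,
        }
        if self.high_dr_ge is not None:
            d["high_dr_ge"] = self.high_dr_ge
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryScheme":
        return cls(
            name=d["name"],
            dr_low_lt=int(d["dr_low_lt"]),
            dq_low_lt=int(d["dq_low_lt"]),
            high_dq_ge=int(d["high_dq_ge"]),
            high_dr_ge=int(d["high_dr_ge"]) if d.get("high_dr_ge") is not None else None,
        )


#: published scheme: LOW if DR<7 and DQ<9; HIGH if DQ>=15
WIEBE = CategoryScheme("wiebe", dr_low_lt=7, dq_low_lt=9, high_dq_ge=15)

#: cohort-specific scheme: same LOW; HIGH if DR>=12 and DQ>=15
NUCOT = CategoryScheme("nucot", dr_low_lt=7, dq_low_lt=9, high_dq_ge=15, high_dr_ge=12)

BUILTIN_SCHEMES = {s.name: s for s in (WIEBE, NUCOT)}


def classify(dr_max: int, dq_max: int, scheme: CategoryScheme) -> RiskCategory:
    if dr_max < 0 or dq_max < 0:
        raise ContractError("mismatch maxima must be non-negative")
    if dr_max < scheme.dr_low_lt and dq_max < scheme.dq_low_lt:
        return RiskCategory.LOW
    if scheme.high_rule(dr_max, dq_max):
        return RiskCategory.HIGH
    return RiskCategory.INTERMEDIATE


def category_proportions(summaries, scheme: CategoryScheme) -> dict:
    """Counts and proportions per category over recipient summaries.

    Accepts any iterable of objects exposing ``dr_max``/``dq_max`` (e.g.
    :class:`~epletmm.mismatch.RecipientMismatchSummary`) or (dr, dq) tuples.
    """
    items = list(summaries)
    if not items:
        raise ContractError("category_proportions requires a non-empty input")
    counts = {c: 0 for c in RiskCategory}
    for item in items:
        if hasattr(item, "dr_max"):
            dr, dq = item.dr_max, item.dq_max
        else:
            dr, dq = item
        counts[classify(dr, dq, scheme)] += 1
    n = len(items)
    return {
        c.name: {"count": counts[c], "proportion": counts[c] / n} for c in RiskCategory
    }
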