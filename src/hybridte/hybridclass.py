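"""Four-category classification of hybrid expression relative to the parents.

Each family in a hybrid is tested against both parental lines; the pair of
DE statuses maps to one of four categories (plus not_de):

* **parentA_like** — DE only vs parent W: the hybrid tracks parent A;
* **parentW_like** — DE only vs parent A: the hybrid tracks parent W;
* **additive** — DE vs both parents in opposite directions: the hybrid sits
  between the parental levels;
* **deregulated** — DE vs both parents in the same direction: the hybrid is
  above or below both parental levels (direction recorded);
* **not_de** — not DE vs either parent.

The five categories partition every possible status pair, and swapping the
parent labels swaps the two parent-like categories while leaving the rest
fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["CategoryCall", "CategorySummary", "classify", "classify_frame", "summarize_categories"]

CATEGORIES = ("parentA_like", "parentW_like", "additive", "deregulated", "not_de")
_DE_STATUSES = ("over", "under", "not_de")


@dataclass(frozen=True)
class CategoryCall:
    family: str
    category: str
    direction: str = "none"  # over/under for deregulated, else none


@dataclass
class CategorySummary:
    counts: dict  # category -> int (classified categories + not_de)
    percentages: dict  # category -> float, over classified families only
    n_classified: int


def classify(status_vs_parent_a: str, status_vs_parent_w: str, family: str = "") -> CategoryCall:
    """Map a hybrid family's two DE statuses to an expression category.

    *status_vs_parent_a* / *status_vs_parent_w* are the DE statuses
    ({over, under, not_de}) of the hybrid-vs-parent contrasts, computed with
    the same thresholds.
    """
    a, w = status_vs_parent_a, status_vs_parent_w
    for name, s in (("status_vs_parent_a", a), ("status_vs_parent_w", w)):
        if s not in _DE_STATUSES:
            raise ValueError(f"{name} must be one of {_DE_STATUSES}, got {s!r}")
    if a == "not_de" and w == "not_de":
        return CategoryCall(family, "not_de")
    if a == "not_de":
        return CategoryCall(family, "parentA_like")
    if w == "not_de":
        return CategoryCall(family, "parentW_like")
    if a == w:
        return CategoryCall(family, "deregulated", direction=a)
    return CategoryCall(family, "additive")


def classify_frame(de_vs_parent_a: pd.DataFrame, de_vs_parent_w: pd.DataFrame) -> pd.DataFrame:
    """Classify every family from two DE result tables (``status`` columns).

    The tables must share their family index. Returns a DataFrame with
    ``category`` and ``direction`` columns.
    """
    if not de_vs_parent_a.index.equals(de_vs_parent_w.index):
        raise ValueError("DE result tables must share the same family index")
    calls = [
        classify(sa, sw, family=str(fam))
        for fam, sa, sw in zip(
            de_vs_parent_a.index, de_vs_parent_a["status"], de_vs_parent_w["status"]
        )
    ]
    return pd.DataFrame(
        {"category": [c.category for c in calls], "direction": [c.direction for c in calls]},
        index=de_vs_parent_a.index,
    )


def _round_half_away(x: float, decimals: int) -> float:
    scale = 10**decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def summarize_categories(calls, decimals: int = 1) -> CategorySummary:
    """Count and percentage per category over families DE vs >= 1 parent.

    *calls* is an iterable of :class:`CategoryCall` or a DataFrame with a
    ``category`` column. Percentages use the classified (non-not_de) family
    total as denominator and round half away from zero at *decimals*.
    With zero classified families the percentages are NaN.
    """
    if isinstance(calls, pd.DataFrame):
        cats = list(calls["category"])
    else:
        cats = [c.category for c in calls]
    counts = {cat: cats.count(cat) for cat in CATEGORIES}
    n_classified = sum(v for k, v in counts.items() if k != "not_de")
    percentages = {}
    for cat in CATEGORIES:
        if cat == "not_de":
            continue
        if n_classified == 0:
            percentages[cat] = float("nan")
        else:
            percentages[cat] = _round_half_away(100.0 * counts[cat] / n_classified, decimals)
    return CategorySummary(counts=counts, percentages=percentages, n_classified=n_classified)
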