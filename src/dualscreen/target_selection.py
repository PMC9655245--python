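"""Receptor-structure selection by docking enrichment and specificity.

Before screening, candidate crystal structures are compared by docking a
labelled test set (known actives vs. inactives/randoms) into each and
asking which structure best separates the classes: the TP/FP enrichment
ratio (docked fraction of actives over docked fraction of inactives) and
the specificity (fraction of inactives correctly rejected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "DockingTestSet",
    "EnrichmentResult",
    "enrichment_ratio",
    "specificity",
    "rank_structures",
]


@dataclass(frozen=True)
class DockingTestSet:
    """Docking outcome counts for one structure."""

    n_actives: int
    docked_actives: int
    n_inactives: int
    docked_inactives: int

    def __post_init__(self) -> None:
        for n, d, what in (
            (self.n_actives, self.docked_actives, "active"),
            (self.n_inactives, self.docked_inactives, "inactive"),
        ):
            if n < 0 or d < 0:
                raise ValueError("counts must be non-negative")
            if d > n:
                raise ValueError(f"docked {what}s ({d}) exceed class size ({n})")


@dataclass(frozen=True)
class EnrichmentResult:
    """TP/FP enrichment and specificity for one structure."""

    tp_rate: float
    fp_rate: float
    ratio: float  # inf when no inactive docked
    specificity: float

    @property
    def ratio_is_finite(self) -> bool:
        return math.isfinite(self.ratio)

    def rounded_ratio(self, sig: int = 2) -> float:
        """Ratio rounded to ``sig`` significant figures (report convention)."""
        if not math.isfinite(self.ratio) or self.ratio == 0:
            return self.ratio
        exp = math.floor(math.log10(abs(self.ratio)))
        return round(self.ratio, sig - 1 - exp)


def enrichment_ratio(ts: DockingTestSet) -> EnrichmentResult:
    """TP/FP ratio = (docked actives / actives) / (docked inactives / inactives).

    When no inactive docks the ratio is flagged infinite and the TP rate is
    still reported.
    """
    if ts.n_actives == 0 or ts.n_inactives == 0:
        raise ValueError("both class sizes must be positive")
    tp_rate = ts.docked_actives / ts.n_actives
    fp_rate = ts.docked_inactives / ts.n_inactives
    ratio = tp_rate / fp_rate if fp_rate > 0 else math.inf
    return EnrichmentResult(
        tp_rate=tp_rate, fp_rate=fp_rate, ratio=ratio, specificity=1.0 - fp_rate
    )


def specificity(n_inactives: int, docked_inactives: int) -> float:
    """Fraction of inactives correctly rejected by docking."""
    if n_inactives <= 0:
        raise ValueError("n_inactives must be positive")
    if docked_inactives > n_inactives:
        raise ValueError("docked inactives exceed class size")
    return (n_inactives - docked_inactives) / n_inactives


def rank_structures(
    results: Mapping[str, EnrichmentResult], criterion: str = "ratio"
) -> list[str]:
    """Structure ids sorted best-first by the chosen criterion.

    Ties are broken by the other criterion, then by structure id.
    """
    if criterion not in ("ratio", "specificity"):
        raise ValueError(f"unknown criterion {criterion!r}")
    other = "specificity" if criterion == "ratio" else "ratio"

    def key(item):
        sid, res = item
        return (-getattr(res, criterion), -getattr(res, other), sid)

    return [sid for sid, _ in sorted(results.items(), key=key)]
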