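"""Blind-assessment ranking and run-vs-run comparison.

Mirrors CASP-style reporting: decoys are ranked by energy score, the
lowest-energy decoy is the "first model", the best GDT among the five
lowest-energy decoys is the "best model", and the mean GDT of those five
is the "top-5 average".  The score-blind best decoy is reported alongside
as an upper bound on what model selection could have achieved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assembly import Decoy
from .geometry import gdt_ts
from .io import BackboneStructure

__all__ = [
    "AssessmentReport",
    "ComparisonSummary",
    "rank_by_score",
    "summarize_blind",
    "blind_report",
    "compare_runs",
]


@dataclass(frozen=True)
class AssessmentReport:
    """First / Best-of-5 / Top-5-average / score-blind-best GDT for a decoy set."""

    first_model_gdt: float
    best_of_5_gdt: float
    top5_avg_gdt: float
    best_decoy_gdt: float
    n_decoys: int

    def __post_init__(self) -> None:
        eps = 1e-9
        if not self.best_decoy_gdt + eps >= self.best_of_5_gdt >= self.top5_avg_gdt - eps:
            raise ValueError("report violates best_decoy >= best_of_5 >= top5_avg")


@dataclass(frozen=True)
class ComparisonSummary:
    """How often and by how much run B beat run A on a per-target GDT field."""

    n_better: int
    n_total: int
    mean_gdt_change_pct: float  # 100 * (mean_B - mean_A) / mean_A
    mean_gdt_change_points: float  # mean_B - mean_A, GDT points

    def __post_init__(self) -> None:
        if not 0 <= self.n_better <= self.n_total:
            raise ValueError("n_better out of range")


def rank_by_score(decoys: Sequence[Decoy]) -> list[Decoy]:
    """Decoys in ascending score order; ties broken by seed for determinism."""
    if not decoys:
        raise ValueError("no decoys to rank")
    return sorted(decoys, key=lambda d: (d.score, d.seed))


def summarize_blind(gdts_in_score_order: Sequence[float]) -> AssessmentReport:
    """Report from per-decoy GDTs already sorted by ascending energy score.

    The first model is the lowest-score decoy; best-of-5 and top-5 average
    use the five lowest-score decoys; the best decoy is score-blind.
    """
    if len(gdts_in_score_order) < 5:
        raise ValueError(f"blind assessment needs >= 5 decoys, got {len(gdts_in_score_order)}")
    top5 = list(gdts_in_score_order[:5])
    return AssessmentReport(
        first_model_gdt=top5[0],
        best_of_5_gdt=max(top5),
        top5_avg_gdt=float(np.mean(top5)),
        best_decoy_gdt=max(gdts_in_score_order),
        n_decoys=len(gdts_in_score_order),
    )


def blind_report(decoys: Sequence[Decoy], native: BackboneStructure) -> AssessmentReport:
    """CASP-style report over a decoy set with a known native structure."""
    if len(decoys) < 5:
        raise ValueError(f"blind assessment needs >= 5 decoys, got {len(decoys)}")
    ranked = rank_by_score(decoys)
    gdts = [gdt_ts(d.conformation.backbone(), native).total for d in ranked]
    return summarize_blind(gdts)


def compare_runs(
    reports_a: dict[str, float], reports_b: dict[str, float]
) -> ComparisonSummary:
    """Per-target comparison of a GDT field between two runs.

    ``n_better`` counts targets where B strictly exceeds A; the mean-GDT
    change is reported both as a relative percentage of A's mean and as
    absolute GDT points.
    """
    if set(reports_a) != set(reports_b):
        only_a = sorted(set(reports_a) - set(reports_b))
        only_b = sorted(set(reports_b) - set(reports_a))
        raise KeyError(f"target sets differ (only in A: {only_a}, only in B: {only_b})")
    if not reports_a:
        raise ValueError("no targets to compare")
    keys = sorted(reports_a)
    a = np.array([reports_a[k] for k in keys], dtype=float)
    b = np.array([reports_b[k] for k in keys], dtype=float)
    n_better = int(np.sum(b > a))
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if mean_a == 0:
        raise ValueError("mean GDT of run A is zero; relative change undefined")
    return ComparisonSummary(
        n_better=n_better,
        n_total=len(keys),
        mean_gdt_change_pct=100.0 * (mean_b - mean_a) / mean_a,
        mean_gdt_change_points=mean_b - mean_a,
    )
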