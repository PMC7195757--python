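"""Empirical fragment-quality statistics that justify the cardinality policy.

For a target of known structure, every candidate fragment can be scored
by the RMSD between its ideal-geometry rebuild and the corresponding
native window.  Aggregating those RMSDs per window (first/best/worst/mean)
and across growing top-m candidate sets (best-of-top-m gain curves) shows
how many candidates each secondary-structure class actually needs: the
count recommended for a class is the smallest set size beyond which every
further enlargement improves the best attainable RMSD by less than a
negligibility threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cardinality import WindowClass, classify_window
from .geometry import build_backbone, kabsch_superpose
from .io import BackboneStructure, FragmentCandidate, FragmentLibrary, SecondaryStructure

__all__ = [
    "PositionStats",
    "GainTable",
    "CountRecommendation",
    "candidate_rmsd",
    "position_stats",
    "select_positions",
    "gain_table",
    "select_count",
    "DEFAULT_M_LIST",
]

DEFAULT_M_LIST = (1, 5, 10, 15, 20, 25, 30, 35, 40)


@dataclass(frozen=True)
class PositionStats:
    """Candidate-RMSD summary for one window: first (rank-1), best, worst, mean."""

    window: int
    rmsd_first: float
    rmsd_best: float
    rmsd_worst: float
    rmsd_mean: float

    def __post_init__(self) -> None:
        eps = 1e-12
        if not (self.rmsd_best <= self.rmsd_first + eps and self.rmsd_best <= self.rmsd_mean + eps):
            raise ValueError("best RMSD must not exceed first or mean")
        if not (self.rmsd_first <= self.rmsd_worst + eps and self.rmsd_mean <= self.rmsd_worst + eps):
            raise ValueError("worst RMSD must bound first and mean")


@dataclass(frozen=True)
class GainTable:
    """Average best-of-top-m RMSD gains between consecutive set sizes.

    ``gains[(n, m)]`` is the mean over the selected positions of
    100 x (best_rmsd(top n) - best_rmsd(top m)) / best_rmsd(top n),
    for consecutive pairs n < m of ``m_list``.  Gains are >= 0 by
    construction (minimum over a superset).
    """

    m_list: tuple[int, ...]
    gains: dict[tuple[int, int], float]
    truncated_positions: tuple[int, ...] = ()  # windows with fewer candidates than max(m_list)

    def consecutive_pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.m_list[:-1], self.m_list[1:]))


@dataclass(frozen=True)
class CountRecommendation:
    """Recommended candidate count for an SS class under threshold tau (%)."""

    ss_class: WindowClass | None
    count: int
    tau: float


def candidate_rmsd(
    candidate: FragmentCandidate, native: BackboneStructure, window_start: int
) -> float:
    """RMSD (A, N/CA/C atoms) of a candidate's ideal-geometry rebuild vs the native window."""
    k = candidate.k
    if not 1 <= window_start <= native.length - k + 1:
        raise IndexError(
            f"window {window_start}..{window_start + k - 1} out of range for L={native.length}"
        )
    frag = build_backbone(candidate.torsions())
    native_atoms = native.backbone_atoms(window_start, window_start + k - 1)
    return kabsch_superpose(frag.backbone_atoms(), native_atoms).rmsd


def _window_rmsds(lib: FragmentLibrary, native: BackboneStructure, window: int) -> np.ndarray:
    try:
        w = lib.windows[window]
    except KeyError:
        raise KeyError(f"library has no window {window}") from None
    return np.array([candidate_rmsd(c, native, window) for c in w.candidates])


def position_stats(
    lib: FragmentLibrary, native: BackboneStructure, window: int
) -> PositionStats:
    """First/best/worst/mean candidate RMSD at one window (first = picker rank 1)."""
    r = _window_rmsds(lib, native, window)
    return PositionStats(
        window=window,
        rmsd_first=float(r[0]),
        rmsd_best=float(r.min()),
        rmsd_worst=float(r.max()),
        rmsd_mean=float(r.mean()),
    )


def select_positions(
    ss: SecondaryStructure, k: int, ss_class: WindowClass
) -> list[int]:
    """All window start indices whose classification equals ``ss_class``."""
    return [
        start
        for start in range(1, len(ss) - k + 2)
        if classify_window(ss, start, k) == ss_class
    ]


def gain_table(
    lib: FragmentLibrary,
    native: BackboneStructure,
    positions: list[int],
    m_list: tuple[int, ...] = DEFAULT_M_LIST,
) -> GainTable:
    """Average relative RMSD gain of best-of-top-m over best-of-top-n, consecutive pairs.

    A position with fewer candidates than max(m_list) contributes its full
    candidate list for any larger m and is flagged in the result.
    """
    if not positions:
        raise ValueError("no positions selected")
    if list(m_list) != sorted(set(m_list)) or m_list[0] < 1:
        raise ValueError("m_list must be strictly increasing positive integers")
    per_pos_rmsds = {p: _window_rmsds(lib, native, p) for p in positions}
    truncated = tuple(p for p, r in per_pos_rmsds.items() if r.size < max(m_list))
    gains: dict[tuple[int, int], float] = {}
    for n, m in zip(m_list[:-1], m_list[1:]):
        vals = []
        for p in positions:
            r = per_pos_rmsds[p]
            best_n = r[: min(n, r.size)].min()
            best_m = r[: min(m, r.size)].min()
            vals.append(0.0 if best_n == 0 else 100.0 * (best_n - best_m) / best_n)
        gains[(n, m)] = float(np.mean(vals))
    return GainTable(m_list=tuple(m_list), gains=gains, truncated_positions=truncated)


def select_count(
    gain: GainTable, tau: float, ss_class: WindowClass | None = None
) -> CountRecommendation:
    """Smallest m in m_list beyond which every consecutive gain is below tau (%).

    Falls back to max(m_list) if even the last enlargement still gains
    tau or more.
    """
    chosen = gain.m_list[-1]
    for m in gain.m_list:
        tail = [gain.gains[(a, b)] for a, b in gain.consecutive_pairs() if a >= m]
        if all(g < tau for g in tail):
            chosen = m
            break
    return CountRecommendation(ss_class=ss_class, count=chosen, tau=tau)
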