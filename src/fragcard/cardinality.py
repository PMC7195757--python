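"""Secondary-structure-conditioned fragment cardinality.

Fragment-assembly tools such as Rosetta draw insertion candidates from
rank-ordered per-window fragment lists (by default 25 9-mers and 200
3-mers per window).  Because the sequence-structure relationship is far
tighter for helices than for strands, and loosest for coil, the number of
candidates actually worth keeping depends on the window's predicted
secondary structure.  This module classifies each k-residue window of a
target as pure helix, pure strand, or mixed, and truncates its candidate
list to an SS-dependent maximum:

===========  ==========  ===========  =====
k            pure helix  pure strand  mixed
===========  ==========  ===========  =====
9-mers            1           25        25
3-mers            5           25       200
===========  ==========  ===========  =====

"Top n" means the first n candidates in file order, which is the picker's
score order; no re-scoring is performed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .io import FragmentLibrary, FragmentWindow, SecondaryStructure

__all__ = [
    "WindowClass",
    "CardinalityPolicy",
    "CardinalityAssignment",
    "CustomizationReport",
    "classify_window",
    "assign_counts",
    "truncate_library",
    "relative_size",
    "customize",
]


class WindowClass(enum.Enum):
    """Secondary-structure composition class of a k-residue window."""

    PURE_HELIX = "helix"
    PURE_STRAND = "strand"
    MIXED = "mixed"


#: Default maximum candidate counts per (fragment length, window class).
DEFAULT_COUNTS: dict[tuple[int, WindowClass], int] = {
    (9, WindowClass.PURE_HELIX): 1,
    (9, WindowClass.PURE_STRAND): 25,
    (9, WindowClass.MIXED): 25,
    (3, WindowClass.PURE_HELIX): 5,
    (3, WindowClass.PURE_STRAND): 25,
    (3, WindowClass.MIXED): 200,
}


@dataclass(frozen=True)
class CardinalityPolicy:
    """Mapping (fragment length, window class) -> maximum candidate count."""

    counts: dict[tuple[int, WindowClass], int] = field(
        default_factory=lambda: dict(DEFAULT_COUNTS)
    )

    def __post_init__(self) -> None:
        for key, v in self.counts.items():
            if v < 1:
                raise ValueError(f"count for {key} must be >= 1, got {v}")

    def count(self, k: int, cls: WindowClass) -> int:
        try:
            return self.counts[(k, cls)]
        except KeyError:
            raise KeyError(f"policy has no count for k={k}, class={cls.value}") from None

    @classmethod
    def standard(cls) -> "CardinalityPolicy":
        """Uniform 25/200 counts: customization becomes the identity."""
        return cls(counts={
            (9, WindowClass.PURE_HELIX): 25,
            (9, WindowClass.PURE_STRAND): 25,
            (9, WindowClass.MIXED): 25,
            (3, WindowClass.PURE_HELIX): 200,
            (3, WindowClass.PURE_STRAND): 200,
            (3, WindowClass.MIXED): 200,
        })

    @classmethod
    def from_mapping(cls, mapping: dict) -> "CardinalityPolicy":
        """Build a policy from a flat ``{"9_helix": 1, ...}`` mapping (e.g. YAML).

        Unspecified keys fall back to the default policy.
        """
        counts = dict(DEFAULT_COUNTS)
        by_name = {c.value: c for c in WindowClass}
        for key, v in mapping.items():
            k_s, _, cls_s = str(key).partition("_")
            if k_s not in ("3", "9") or cls_s not in by_name:
                raise ValueError(
                    f"bad policy key {key!r}; expected '<3|9>_<helix|strand|mixed>'"
                )
            counts[(int(k_s), by_name[cls_s])] = int(v)
        return cls(counts=counts)


@dataclass(frozen=True)
class CardinalityAssignment:
    """Per-window class and maximum count for one fragment length."""

    k: int
    entries: tuple[tuple[int, WindowClass, int], ...]  # (window index, class, count)

    def count(self, window: int) -> int:
        for idx, _, n in self.entries:
            if idx == window:
                return n
        raise KeyError(f"no entry for window {window}")

    def window_indices(self) -> list[int]:
        return [idx for idx, _, _ in self.entries]

    def class_tally(self) -> dict[WindowClass, int]:
        tally = {c: 0 for c in WindowClass}
        for _, cls, _ in self.entries:
            tally[cls] += 1
        return tally


def classify_window(ss: SecondaryStructure, start: int, k: int) -> WindowClass:
    """Classify the k-residue window beginning at 1-based position ``start``."""
    if not 1 <= start <= len(ss) - k + 1:
        raise IndexError(
            f"window start {start} out of range 1..{len(ss) - k + 1} for L={len(ss)}, k={k}"
        )
    window = ss.symbols[start - 1 : start - 1 + k]
    if window == "H" * k:
        return WindowClass.PURE_HELIX
    if window == "E" * k:
        return WindowClass.PURE_STRAND
    return WindowClass.MIXED


def assign_counts(
    ss: SecondaryStructure, k: int, policy: CardinalityPolicy | None = None
) -> CardinalityAssignment:
    """Assign a maximum candidate count to every window 1..L-k+1."""
    if policy is None:
        policy = CardinalityPolicy()
    if len(ss) < k:
        raise ValueError(f"target length {len(ss)} shorter than fragment length {k}")
    entries = []
    for start in range(1, len(ss) - k + 2):
        cls = classify_window(ss, start, k)
        entries.append((start, cls, policy.count(k, cls)))
    return CardinalityAssignment(k=k, entries=tuple(entries))


def truncate_library(
    lib: FragmentLibrary, assignment: CardinalityAssignment
) -> FragmentLibrary:
    """Keep each window's first min(count, available) candidates, in rank order."""
    if assignment.k != lib.k:
        raise ValueError(f"assignment is for {assignment.k}-mers, library holds {lib.k}-mers")
    if assignment.window_indices() != lib.window_indices():
        raise ValueError(
            f"window sets differ: assignment {assignment.window_indices()[:5]}... vs "
            f"library {lib.window_indices()[:5]}..."
        )
    windows = {}
    for idx, _, count in assignment.entries:
        w = lib.windows[idx]
        windows[idx] = FragmentWindow(index=idx, candidates=list(w.candidates[:count]))
    return FragmentLibrary(k=lib.k, seq_len=lib.seq_len, windows=windows)


def relative_size(new: FragmentLibrary, old: FragmentLibrary) -> float:
    """Size of a truncated library as a percentage of the original, one decimal.

    100 x (total candidates in ``new``) / (total candidates in ``old``),
    rounded half-up to one decimal place.
    """
    if new.k != old.k or new.window_indices() != old.window_indices():
        raise ValueError("libraries must share fragment length and window set")
    denom = old.total_candidates()
    if denom == 0:
        raise ValueError("old library is empty")
    pct = 100.0 * new.total_candidates() / denom
    # round half-up to one decimal (Python's round is half-even)
    import math

    return math.floor(pct * 10 + 0.5) / 10


@dataclass(frozen=True)
class CustomizationReport:
    """Sizes and per-class window tallies from one customization run."""

    rel_size_9mer: float
    rel_size_3mer: float
    tally_9mer: dict[WindowClass, int]
    tally_3mer: dict[WindowClass, int]


def customize(
    frag9: FragmentLibrary,
    frag3: FragmentLibrary,
    ss: SecondaryStructure,
    policy: CardinalityPolicy | None = None,
) -> tuple[FragmentLibrary, FragmentLibrary, CustomizationReport]:
    """Truncate a target's 9-mer and 3-mer libraries per its secondary structure."""
    if policy is None:
        policy = CardinalityPolicy()
    if frag9.seq_len != len(ss) or frag3.seq_len != len(ss):
        raise ValueError(
            f"length mismatch: 9-mer library {frag9.seq_len}, 3-mer library "
            f"{frag3.seq_len}, SS {len(ss)}"
        )
    a9 = assign_counts(ss, 9, policy)
    a3 = assign_counts(ss, 3, policy)
    new9 = truncate_library(frag9, a9)
    new3 = truncate_library(frag3, a3)
    report = CustomizationReport(
        rel_size_9mer=relative_size(new9, frag9),
        rel_size_3mer=relative_size(new3, frag3),
        tally_9mer=a9.class_tally(),
        tally_3mer=a3.class_tally(),
    )
    return new9, new3, report
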