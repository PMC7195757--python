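"""Synthetic natives, rank-ordered noisy fragment libraries, and the 24-target table.

Everything the test and demonstration pipelines need is generated here,
without downloads.  Native structures are ideal-geometry backbones built
from canonical torsion basins; fragment libraries are test doubles for
picker output in which candidate quality degrades with rank (rank-1
candidates are near-native, emulating the empirical behaviour observed
for helical fragments).  Homolog exclusion is not modeled: synthetic
libraries are by construction non-homologous.

The 24-row study-dataset table (PDB id, length, SS composition, and the
relative sizes of the customized 9-mer/3-mer fragment files) is packaged
as a transcription fixture for statistics tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import build_backbone
from .io import (
    BackboneStructure,
    FragmentCandidate,
    FragmentLibrary,
    FragmentWindow,
    ResidueRecord,
    SecondaryStructure,
    wrap_angle,
)

__all__ = [
    "NoiseModel",
    "Table1Row",
    "ToyTarget",
    "ideal_structure",
    "noisy_library",
    "table1_fixture",
    "toy_target_suite",
    "HELIX_TORSIONS",
    "STRAND_TORSIONS",
]

HELIX_TORSIONS = (-57.0, -47.0, 180.0)
STRAND_TORSIONS = (-119.0, 113.0, 180.0)

# crude Ramachandran coil proxy: phi uniform in (-160, -50),
# psi uniform over (60, 180) union (-180, -150)
_COIL_PHI = (-160.0, -50.0)
_COIL_PSI_SPAN = 150.0  # 120 degrees in (60, 180) + 30 degrees in (-180, -150)


@dataclass(frozen=True)
class NoiseModel:
    """Rank-degrading torsion noise for synthetic picker output.

    Candidate at rank r gets Gaussian torsion noise with sd
    sigma0 * (1 + alpha * (r - 1)) degrees; with probability
    ``decoy_fraction`` a candidate of rank >= 2 is drawn from a wrong-SS
    torsion basin instead (rank 1 is always basin-correct, emulating the
    observed reliability of top-ranked fragments).
    """

    sigma0: float = 2.0
    alpha: float = 0.4
    decoy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.alpha < 0:
            raise ValueError("sigma0 and alpha must be >= 0")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must be in [0, 1)")


@dataclass(frozen=True)
class Table1Row:
    """One target of the 24-protein study dataset."""

    pdb_id: str
    length: int
    pct_helix: float
    pct_strand: float
    pct_coil: float
    rel_size_9mer: float
    rel_size_3mer: float
    hard_flag: bool


# (pdb_id, length, %H, %E, %C, rel 9-mer %, rel 3-mer %, hard)
_TABLE1 = (
    ("2CI2_I", 65, 16, 21, 63, 85.8, 51.7, False),
    ("1CTF", 68, 51, 24, 25, 85.2, 49.7, False),
    ("1DI2", 69, 46, 33, 21, 89.5, 47.8, False),
    ("1SCJ_B", 71, 23, 39, 38, 86.5, 49.5, False),
    ("1HZ5", 72, 30, 38, 32, 79.2, 37.0, False),
    ("1CC8", 72, 28, 35, 37, 88.2, 55.3, False),
    ("3NZL", 73, 59, 0, 41, 79.5, 41.4, False),
    ("1DTJ", 74, 38, 26, 36, 88.4, 51.8, False),
    ("1IG5", 75, 61, 5, 34, 83.5, 47.6, False),
    ("1OGW", 76, 25, 34, 41, 81.4, 47.9, False),
    ("1DCJ", 81, 28, 24, 48, 77.8, 40.5, False),
    ("1TIG", 88, 32, 32, 36, 50.0, 29.7, False),
    ("1A19", 89, 43, 17, 40, 92.9, 61.5, False),
    ("1BM8", 99, 37, 27, 36, 93.9, 58.4, False),
    ("4UBP", 100, 54, 17, 29, 77.2, 46.5, False),
    ("1IIB", 103, 55, 19, 26, 94.9, 73.4, False),
    ("1M6T", 106, 77, 0, 23, 84.8, 50.1, False),
    ("1ACF", 125, 34, 32, 34, 77.8, 45.1, False),
    ("3CHY", 128, 45, 17, 38, 73.9, 45.3, False),
    ("2KDL", 56, 62, 0, 38, 87.7, 50.2, True),
    ("2LR8", 70, 57, 0, 43, 74.0, 44.0, True),
    ("4HLB", 95, 28, 24, 48, 78.2, 49.6, True),
    ("2K4V", 125, 28, 32, 40, 72.1, 48.4, True),
    ("2KY4", 149, 59, 1, 40, 87.9, 54.1, True),
)


def table1_fixture() -> list[Table1Row]:
    """The 24-row study dataset, transcribed exactly as printed."""
    return [Table1Row(*row) for row in _TABLE1]


def _coil_torsions(rng: np.random.Generator) -> tuple[float, float, float]:
    phi = rng.uniform(*_COIL_PHI)
    u = rng.uniform(0.0, _COIL_PSI_SPAN)
    psi = 60.0 + u if u < 120.0 else -180.0 + (u - 120.0)
    return phi, psi, 180.0


def ideal_torsions(ss: SecondaryStructure, seed: int = 0) -> np.ndarray:
    """Per-residue torsions for an ideal native: canonical H/E basins, seeded coil."""
    rng = np.random.default_rng(seed)
    out = np.empty((len(ss), 3))
    for i, s in enumerate(ss.symbols):
        if s == "H":
            out[i] = HELIX_TORSIONS
        elif s == "E":
            out[i] = STRAND_TORSIONS
        else:
            out[i] = _coil_torsions(rng)
    return out


def ideal_structure(ss: SecondaryStructure, seed: int = 0) -> BackboneStructure:
    """Ideal-geometry native backbone realizing the given secondary structure."""
    return build_backbone(ideal_torsions(ss, seed=seed))


def _wrong_basin(window_ss: str) -> tuple[float, float, float]:
    """A torsion basin different from the window's dominant SS."""
    return STRAND_TORSIONS if window_ss.count("H") >= window_ss.count("E") else HELIX_TORSIONS


def noisy_library(
    native: BackboneStructure,
    ss: SecondaryStructure,
    k: int,
    n_candidates: int,
    noise: NoiseModel | None = None,
) -> FragmentLibrary:
    """Rank-ordered noisy fragment library around a native structure.

    For each window, candidate rank r carries the native window torsions
    perturbed by Gaussian noise of sd sigma0 * (1 + alpha * (r - 1))
    degrees, wrapped to (-180, 180]; record SS labels always match the
    native annotation.
    """
    if n_candidates < 1:
        raise ValueError("need at least one candidate per window")
    if native.length != len(ss):
        raise ValueError(f"native length {native.length} != SS length {len(ss)}")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    from .geometry import extract_torsions

    native_torsions = extract_torsions(native)
    # terminal sentinels are inert in fragments; replace for arithmetic
    native_torsions = np.nan_to_num(native_torsions, nan=180.0)

    L = native.length
    windows: dict[int, FragmentWindow] = {}
    for start in range(1, L - k + 2):
        win_t = native_torsions[start - 1 : start - 1 + k]
        win_ss = ss.symbols[start - 1 : start - 1 + k]
        candidates = []
        for r in range(1, n_candidates + 1):
            if r > 1 and noise.decoy_fraction > 0 and rng.random() < noise.decoy_fraction:
                base = np.tile(_wrong_basin(win_ss), (k, 1))
                t = base + rng.normal(0.0, noise.sigma0 + 1e-9, size=(k, 3))
            else:
                sd = noise.sigma0 * (1.0 + noise.alpha * (r - 1))
                t = win_t + rng.normal(0.0, sd + 1e-9, size=(k, 3))
            records = tuple(
                ResidueRecord(
                    source_id="synt",
                    chain="A",
                    resseq=start + j,
                    aa="A",
                    ss="L" if win_ss[j] == "C" else win_ss[j],
                    phi=wrap_angle(t[j, 0]),
                    psi=wrap_angle(t[j, 1]),
                    omega=wrap_angle(t[j, 2]),
                )
                for j in range(k)
            )
            candidates.append(FragmentCandidate(records=records))
        windows[start] = FragmentWindow(index=start, candidates=candidates)
    return FragmentLibrary(k=k, seq_len=L, windows=windows)


@dataclass(frozen=True)
class ToyTarget:
    """One synthetic benchmark target: annotation, native, and both libraries."""

    name: str
    ss: SecondaryStructure
    native: BackboneStructure
    lib9: FragmentLibrary
    lib3: FragmentLibrary


# SS composition templates for the toy benchmark: helix-rich, strand-rich, mixed.
_SUITE_PATTERNS = (
    ("helix30", "CC" + "H" * 12 + "CC" + "H" * 12 + "CC"),
    ("helix36", "CCC" + "H" * 14 + "CCC" + "H" * 13 + "CCC"),
    ("helix48", "CC" + "H" * 16 + "CCC" + "H" * 11 + "CCC" + "H" * 11 + "CC"),
    ("helix60", "CCC" + "H" * 18 + "CCCC" + "H" * 16 + "CCC" + "H" * 13 + "CCC"),
    ("strand30", "CC" + "E" * 6 + "CCC" + "E" * 6 + "CCC" + "E" * 7 + "CCC"),
    ("strand38", "CC" + "E" * 7 + "CCC" + "E" * 6 + "CCC" + "E" * 7 + "CCC" + "E" * 4 + "CCC"),
    ("strand48", "CCC" + ("E" * 6 + "CCC") * 5),
    ("mixed34", "CC" + "H" * 11 + "CCC" + "E" * 5 + "CCC" + "E" * 5 + "CCCCC"),
    ("mixed42", "CC" + "E" * 5 + "CCC" + "H" * 13 + "CCC" + "E" * 5 + "CCC" + "H" * 5 + "CCC"),
    ("mixed48", "CCC" + "H" * 14 + "CCC" + "E" * 6 + "CCC" + "E" * 6 + "CCC" + "H" * 7 + "CCC"),
    ("mixed54", "CC" + "H" * 16 + "CCC" + "E" * 7 + "CCCC" + "H" * 12 + "CCC" + "E" * 4 + "CCC"),
    ("mixed60", "CCC" + "H" * 18 + "CCC" + "E" * 7 + "CCC" + "E" * 7 + "CCC" + "H" * 13 + "CCC"),
)

#: Study-condition library sizes for the desk-scale toy benchmark.
SUITE_N_9MER = 25
SUITE_N_3MER = 50
SUITE_NOISE = NoiseModel(sigma0=2.0, alpha=0.4, decoy_fraction=0.05)


def toy_target_suite(seed: int = 0) -> list[ToyTarget]:
    """Twelve synthetic targets (length 30-60) with rank-degrading libraries.

    Used by the end-to-end policy-comparison experiment; regenerating
    with the same seed yields an identical suite.
    """
    targets = []
    for i, (name, pattern) in enumerate(_SUITE_PATTERNS):
        ss = SecondaryStructure(symbols=pattern)
        sub = np.random.SeedSequence([seed, i]).generate_state(3) % (2**31)
        native = ideal_structure(ss, seed=int(sub[0]))
        noise9 = NoiseModel(
            sigma0=SUITE_NOISE.sigma0, alpha=SUITE_NOISE.alpha,
            decoy_fraction=SUITE_NOISE.decoy_fraction, seed=int(sub[1]),
        )
        noise3 = NoiseModel(
            sigma0=SUITE_NOISE.sigma0, alpha=SUITE_NOISE.alpha,
            decoy_fraction=SUITE_NOISE.decoy_fraction, seed=int(sub[2]),
        )
        lib9 = noisy_library(native, ss, k=9, n_candidates=SUITE_N_9MER, noise=noise9)
        lib3 = noisy_library(native, ss, k=3, n_candidates=SUITE_N_3MER, noise=noise3)
        targets.append(ToyTarget(name=name, ss=ss, native=native, lib9=lib9, lib3=lib3))
    return targets
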