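"""Rigid-body superposition, RMSD, GDT_TS, and torsion/Cartesian backbone conversion.

Backbone chains are built from (phi, psi, omega) torsions by sequential
natural-extension placement (NeRF) using fixed ideal bond lengths and
angles; the inverse is standard dihedral extraction.  GDT_TS follows the
CASP definition — the mean over 1/2/4/8 A thresholds of the percentage of
CA atoms within threshold of the native after superposition — with a
documented deterministic LGA-style search heuristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .io import BackboneStructure

__all__ = [
    "IdealGeometry",
    "Superposition",
    "GdtResult",
    "kabsch_superpose",
    "rmsd",
    "gdt_ts",
    "build_backbone",
    "build_ca_trace",
    "extract_torsions",
    "dihedral",
]

#: Sentinel for geometrically undefined terminal torsions.
UNDEFINED_TORSION = np.nan

GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class IdealGeometry:
    """Fixed ideal backbone covalent geometry (lengths in A, angles in degrees)."""

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    omega_default: float = 180.0


IDEAL = IdealGeometry()


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid map x -> rotation @ x + translation of mobile onto reference."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass(frozen=True)
class GdtResult:
    """Per-threshold GDT percentages and their mean (GDT_TS)."""

    p1: float
    p2: float
    p4: float
    p8: float

    @property
    def total(self) -> float:
        return (self.p1 + self.p2 + self.p4 + self.p8) / 4.0

    def as_dict(self) -> dict[str, float]:
        return {"p1": self.p1, "p2": self.p2, "p4": self.p4, "p8": self.p8, "total": self.total}


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    Reflections are excluded (the rotation has determinant +1).  Requires
    at least 3 points; a degenerate (e.g. perfectly collinear) set still
    yields the optimal proper rotation up to the unresolved axis, which
    leaves the RMSD unchanged.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {mobile.shape} vs {reference.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    if not (np.isfinite(mobile).all() and np.isfinite(reference).all()):
        raise ValueError("non-finite coordinates")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    with warnings.catch_warnings():
        # symmetric/degenerate sets trigger a uniqueness warning; the RMSD is still optimal
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    matrix = rot.as_matrix()
    value = float(rssd) / np.sqrt(mobile.shape[0])
    return Superposition(rotation=matrix, translation=rc - matrix @ mc, rmsd=value)


def rmsd(mobile: np.ndarray, reference: np.ndarray, superpose: bool = True) -> float:
    """RMSD in A between corresponding points, optionally after optimal superposition."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if superpose:
        return kabsch_superpose(mobile, reference).rmsd
    if mobile.shape != reference.shape:
        raise ValueError("point sets must share shape")
    return float(np.sqrt(np.mean(np.sum((mobile - reference) ** 2, axis=1))))


def _gdt_fraction(model_ca: np.ndarray, native_ca: np.ndarray, threshold: float) -> float:
    """Best fraction under one threshold via iterative superpose-and-trim from several seeds."""
    n = model_ca.shape[0]
    seeds: list[np.ndarray] = [np.arange(n)]
    seg = 20
    if n > seg:
        for start in range(0, n - seg + 1):
            seeds.append(np.arange(start, start + seg))
    best = 0.0
    for seed in seeds:
        kept = seed
        for _ in range(10):
            if kept.size < 3:
                break
            sup = kabsch_superpose(model_ca[kept], native_ca[kept])
            d = np.linalg.norm(sup.apply(model_ca) - native_ca, axis=1)
            new_kept = np.where(d < threshold)[0]
            frac = new_kept.size / n
            if frac > best:
                best = frac
            if new_kept.size == kept.size and np.array_equal(new_kept, kept):
                break
            kept = new_kept
    return best


def gdt_ts(
    model: BackboneStructure | np.ndarray,
    native: BackboneStructure | np.ndarray,
    mode: str = "search",
) -> GdtResult:
    """CA-based GDT_TS of ``model`` against ``native``.

    ``mode="search"`` superposes with the iterative trim heuristic (seeds:
    all residues plus every contiguous 20-residue segment; per threshold,
    iterate keep-under-threshold / re-superpose to convergence, max 10
    rounds, report the best percentage found).  ``mode="fixed_frame"``
    counts distances in the given frame without any superposition.
    """
    model_ca = model.ca if isinstance(model, BackboneStructure) else np.asarray(model, dtype=float)
    native_ca = native.ca if isinstance(native, BackboneStructure) else np.asarray(native, dtype=float)
    if model_ca.shape != native_ca.shape:
        raise ValueError(
            f"residue count mismatch: model {model_ca.shape[0]}, native {native_ca.shape[0]}"
        )
    if mode == "fixed_frame":
        d = np.linalg.norm(model_ca - native_ca, axis=1)
        pcts = [100.0 * np.mean(d < t) for t in GDT_THRESHOLDS]
    elif mode == "search":
        pcts = [100.0 * _gdt_fraction(model_ca, native_ca, t) for t in GDT_THRESHOLDS]
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'search' or 'fixed_frame'")
    return GdtResult(p1=pcts[0], p2=pcts[1], p4=pcts[2], p8=pcts[3])


# ---------------------------------------------------------------------------
# Torsion <-> Cartesian

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d given chain a-b-c, |c-d|, angle(b,c,d) and dihedral(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else float(ang)


def build_backbone(torsions: np.ndarray, geometry: IdealGeometry = IDEAL) -> BackboneStructure:
    """Build an ideal-geometry backbone from per-residue (phi, psi, omega) degrees.

    Residue 1 is seeded canonically: N at the origin, CA on +x, C in the
    xy-plane.  phi of residue 1 and psi/omega of the last residue do not
    influence the result (NaN is accepted there).
    """
    torsions = np.asarray(torsions, dtype=float)
    if torsions.ndim != 2 or torsions.shape[1] != 3:
        raise ValueError("torsions must be (L, 3): per-residue (phi, psi, omega)")
    L = torsions.shape[0]
    if L < 1:
        raise ValueError("need at least one residue")
    interior = torsions[1:, 0], torsions[:-1, 1], torsions[:-1, 2]
    if any(not np.isfinite(t).all() for t in interior):
        raise ValueError("non-finite interior torsion angle")

    g = geometry
    n = np.empty((L, 3))
    ca = np.empty((L, 3))
    c = np.empty((L, 3))
    n[0] = (0.0, 0.0, 0.0)
    ca[0] = (g.bond_n_ca, 0.0, 0.0)
    ang = np.deg2rad(g.angle_n_ca_c)
    c[0] = ca[0] + g.bond_ca_c * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, L):
        phi_i = torsions[i, 0]
        psi_prev, omega_prev = torsions[i - 1, 1], torsions[i - 1, 2]
        n[i] = _place_atom(n[i - 1], ca[i - 1], c[i - 1], g.bond_c_n, g.angle_ca_c_n, psi_prev)
        ca[i] = _place_atom(ca[i - 1], c[i - 1], n[i], g.bond_n_ca, g.angle_c_n_ca, omega_prev)
        c[i] = _place_atom(c[i - 1], n[i], ca[i], g.bond_ca_c, g.angle_n_ca_c, phi_i)
    return BackboneStructure(n=n, ca=ca, c=c)


def build_ca_trace(torsions: np.ndarray, geometry: IdealGeometry = IDEAL) -> np.ndarray:
    """CA coordinates only, for scoring loops; same construction as build_backbone."""
    return build_backbone(torsions, geometry).ca


def extract_torsions(structure: BackboneStructure) -> np.ndarray:
    """Per-residue (phi, psi, omega) in degrees; undefined terminal angles are NaN."""
    L = structure.length
    if L < 2:
        raise ValueError("need at least 2 residues to define torsions")
    n, ca, c = structure.n, structure.ca, structure.c
    if not (np.isfinite(n).all() and np.isfinite(ca).all() and np.isfinite(c).all()):
        raise ValueError("non-finite backbone coordinates")
    out = np.full((L, 3), UNDEFINED_TORSION)
    for i in range(L):
        if i > 0:
            out[i, 0] = dihedral(c[i - 1], n[i], ca[i], c[i])  # phi
        if i < L - 1:
            out[i, 1] = dihedral(n[i], ca[i], c[i], n[i + 1])  # psi
            out[i, 2] = dihedral(ca[i], c[i], n[i + 1], ca[i + 1])  # omega
    return out
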