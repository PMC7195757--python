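"""Coarse-grained fragment-assembly simulator.

Starting from a fully extended chain, fragment insertion proceeds by
simulated annealing: at each attempt a window is drawn uniformly at
random, one of its available candidates is drawn uniformly, the window's
torsions are replaced by the candidate's, and the move is kept if it
lowers the surrogate energy or passes the Metropolis criterion at the
current temperature.  A 9-mer phase (default 28,000 attempts) is followed
by a 3-mer phase (default 8,000), with the temperature decaying
geometrically across each phase.

The energy is a deliberately simple surrogate with three terms — steric
clash between CA pairs, deviation of the radius of gyration from a
globular target, and disagreement between per-residue torsion bins and
the target secondary structure — sufficient to make fragment choice
matter while remaining fast and fully documented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .geometry import IDEAL, IdealGeometry, build_backbone
from .io import BackboneStructure, FragmentLibrary, SecondaryStructure

__all__ = [
    "Conformation",
    "ScoreWeights",
    "AnnealSchedule",
    "Decoy",
    "extended_chain",
    "insert_fragment",
    "score",
    "metropolis_accept",
    "run_protocol",
    "generate_decoys",
]

EXTENDED_TORSIONS = (-135.0, 135.0, 180.0)

# torsion bins for the SS-agreement term (phi, psi in degrees)
_HELIX_BIN = ((-100.0, -30.0), (-80.0, -5.0))
_STRAND_BIN = ((-180.0, -90.0), (90.0, 180.0))


@dataclass
class Conformation:
    """Backbone state in torsion space with a lazily rebuilt CA cache."""

    torsions: np.ndarray  # (L, 3) phi, psi, omega degrees
    _ca: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.torsions = np.asarray(self.torsions, dtype=float)
        if self.torsions.ndim != 2 or self.torsions.shape[1] != 3:
            raise ValueError("torsions must be (L, 3)")

    @property
    def length(self) -> int:
        return self.torsions.shape[0]

    @property
    def ca_coords(self) -> np.ndarray:
        if self._ca is None:
            self._ca = _fast_ca_trace(self.torsions)
        return self._ca

    def backbone(self) -> BackboneStructure:
        return build_backbone(self.torsions)

    def copy(self) -> "Conformation":
        return Conformation(torsions=self.torsions.copy())


@dataclass(frozen=True)
class ScoreWeights:
    """Weights and parameters of the surrogate energy."""

    clash: float = 1.0
    clash_radius: float = 4.0  # A, CA-CA
    rg: float = 0.1
    rg_coeff: float = 2.2  # target Rg = rg_coeff * L**0.38
    ss: float = 1.0

    def __post_init__(self) -> None:
        if min(self.clash, self.rg, self.ss) < 0:
            raise ValueError("weights must be >= 0")


@dataclass(frozen=True)
class AnnealSchedule:
    """Insertion-attempt budgets and geometric temperature decay per phase."""

    attempts_9mer: int = 28000
    attempts_3mer: int = 8000
    t_start: float = 2.0
    t_end: float = 0.1

    def __post_init__(self) -> None:
        if self.attempts_9mer < 0 or self.attempts_3mer < 0:
            raise ValueError("attempt counts must be >= 0")
        if not self.t_start >= self.t_end > 0:
            raise ValueError("need t_start >= t_end > 0")

    def temperature(self, i: int, n_attempts: int) -> float:
        """Temperature at attempt i (0-based) of a phase with n_attempts total."""
        if n_attempts <= 1:
            return self.t_start
        ratio = self.t_end / self.t_start
        return self.t_start * ratio ** (i / (n_attempts - 1))


@dataclass(frozen=True)
class Decoy:
    """One finished assembly run."""

    conformation: Conformation
    score: float
    seed: int
    accepted_9mer: int
    accepted_3mer: int


# ---------------------------------------------------------------------------
# fast CA trace (scalar NeRF; cross-checked against geometry.build_backbone)

_SIN_CACHE: dict[tuple[float, ...], tuple] = {}


def _geom_consts(g: IdealGeometry):
    key = (g.bond_n_ca, g.bond_ca_c, g.bond_c_n, g.angle_n_ca_c, g.angle_ca_c_n, g.angle_c_n_ca)
    hit = _SIN_CACHE.get(key)
    if hit is None:
        hit = tuple(
            (b, math.cos(math.radians(a)), math.sin(math.radians(a)))
            for b, a in (
                (g.bond_c_n, g.angle_ca_c_n),
                (g.bond_n_ca, g.angle_c_n_ca),
                (g.bond_ca_c, g.angle_n_ca_c),
            )
        )
        _SIN_CACHE[key] = hit
    return hit


def _fast_ca_trace(torsions: np.ndarray, geometry: IdealGeometry = IDEAL) -> np.ndarray:
    """CA coordinates from torsions using scalar-arithmetic NeRF."""
    L = torsions.shape[0]
    g = geometry
    (b_cn, cos_cacn, sin_cacn), (b_nca, cos_cnca, sin_cnca), (b_cac, cos_ncac, sin_ncac) = \
        _geom_consts(g)
    ca_out = np.empty((L, 3))
    # canonical seed: N at origin, CA on +x, C in xy-plane
    ax, ay, az = 0.0, 0.0, 0.0                      # N_1
    bx, by, bz = g.bond_n_ca, 0.0, 0.0             # CA_1
    cx = bx - g.bond_ca_c * cos_ncac
    cy = g.bond_ca_c * sin_ncac
    cz = 0.0                                        # C_1
    ca_out[0] = (bx, by, bz)
    t = torsions
    for i in range(1, L):
        # atoms to place: N_i (psi_{i-1}), CA_i (omega_{i-1}), C_i (phi_i)
        for (bond, cos_a, sin_a), tor in (
            ((b_cn, cos_cacn, sin_cacn), t[i - 1, 1]),
            ((b_nca, cos_cnca, sin_cnca), t[i - 1, 2]),
            ((b_cac, cos_ncac, sin_ncac), t[i, 0]),
        ):
            bcx, bcy, bcz = cx - bx, cy - by, cz - bz
            inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
            bcx *= inv; bcy *= inv; bcz *= inv
            abx, aby, abz = bx - ax, by - ay, bz - az
            nx = aby * bcz - abz * bcy
            ny = abz * bcx - abx * bcz
            nz = abx * bcy - aby * bcx
            inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
            nx *= inv; ny *= inv; nz *= inv
            mx = ny * bcz - nz * bcy
            my = nz * bcx - nx * bcz
            mz = nx * bcy - ny * bcx
            rad = math.radians(tor)
            d0 = -bond * cos_a
            d1 = bond * sin_a * math.cos(rad)
            d2 = bond * sin_a * math.sin(rad)
            dx = cx + d0 * bcx + d1 * mx + d2 * nx
            dy = cy + d0 * bcy + d1 * my + d2 * ny
            dz = cz + d0 * bcz + d1 * mz + d2 * nz
            ax, ay, az = bx, by, bz
            bx, by, bz = cx, cy, cz
            cx, cy, cz = dx, dy, dz
        # after the three placements, b holds CA_i
        ca_out[i] = (bx, by, bz)
    return ca_out


# ---------------------------------------------------------------------------

def extended_chain(length: int) -> Conformation:
    """Fully extended chain: every residue at (phi, psi, omega) = (-135, 135, 180)."""
    if length < 3:
        raise ValueError("chain needs at least 3 residues")
    return Conformation(torsions=np.tile(EXTENDED_TORSIONS, (length, 1)))


def insert_fragment(conf: Conformation, window_start: int, torsions: np.ndarray) -> Conformation:
    """Replace the torsions of residues window_start..window_start+k-1 (1-based).

    ``torsions`` may be a FragmentCandidate's (k, 3) torsion array.  The
    input conformation is not modified.
    """
    torsions = np.asarray(torsions, dtype=float)
    k = torsions.shape[0]
    if not 1 <= window_start <= conf.length - k + 1:
        raise IndexError(
            f"window {window_start}..{window_start + k - 1} out of range for L={conf.length}"
        )
    new = conf.torsions.copy()
    new[window_start - 1 : window_start - 1 + k] = torsions
    return Conformation(torsions=new)


def _ss_mismatch_fraction(torsions: np.ndarray, ss_codes: np.ndarray) -> float:
    phi = torsions[:, 0]
    psi = torsions[:, 1]
    in_helix = (
        (phi > _HELIX_BIN[0][0]) & (phi < _HELIX_BIN[0][1])
        & (psi > _HELIX_BIN[1][0]) & (psi < _HELIX_BIN[1][1])
    )
    in_strand = (
        (phi >= _STRAND_BIN[0][0]) & (phi < _STRAND_BIN[0][1])
        & (psi >= _STRAND_BIN[1][0]) & (psi <= _STRAND_BIN[1][1])
    )
    bins = np.where(in_helix, 0, np.where(in_strand, 1, 2))
    return float(np.mean(bins != ss_codes))


_SS_CODE = {"H": 0, "E": 1, "C": 2}

_PAIR_MASKS: dict[int, np.ndarray] = {}


def _pair_mask(length: int) -> np.ndarray:
    """Boolean mask into pdist's condensed vector selecting |i-j| >= 3 pairs."""
    mask = _PAIR_MASKS.get(length)
    if mask is None:
        ii, jj = np.triu_indices(length, k=1)
        mask = (jj - ii) >= 3
        _PAIR_MASKS[length] = mask
    return mask


def ss_codes(ss: SecondaryStructure) -> np.ndarray:
    return np.array([_SS_CODE[s] for s in ss.symbols], dtype=np.int8)


def score(
    conf: Conformation,
    ss: SecondaryStructure | np.ndarray,
    weights: ScoreWeights | None = None,
) -> float:
    """Surrogate energy of a conformation; finite, lower is better.

    clash  = sum over CA pairs |i-j| >= 3 of max(0, r_clash - d)^2
    rg     = (Rg - rg_coeff * L^0.38)^2
    ss     = fraction of residues whose (phi, psi) bin disagrees with the target SS
    """
    if weights is None:
        weights = ScoreWeights()
    codes = ss if isinstance(ss, np.ndarray) else ss_codes(ss)
    if conf.length != codes.shape[0]:
        raise ValueError(f"conformation length {conf.length} != SS length {codes.shape[0]}")
    ca = conf.ca_coords
    L = conf.length

    total = 0.0
    if weights.clash > 0:
        d = pdist(ca)
        near = d[_pair_mask(L)]  # pairs with |i-j| >= 3
        viol = weights.clash_radius - near
        viol = viol[viol > 0]
        total += weights.clash * float(np.sum(viol * viol))
    if weights.rg > 0:
        centred = ca - ca.mean(axis=0)
        rg = math.sqrt(float(np.mean(np.sum(centred * centred, axis=1))))
        target = weights.rg_coeff * L ** 0.38
        total += weights.rg * (rg - target) ** 2
    if weights.ss > 0:
        total += weights.ss * _ss_mismatch_fraction(conf.torsions, codes)
    return total


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept downhill moves always; uphill with probability exp(-dE/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / temperature)


def _phase(
    torsions: np.ndarray,
    cand_torsions: list[list[np.ndarray]],
    window_starts: np.ndarray,
    k: int,
    codes: np.ndarray,
    weights: ScoreWeights,
    schedule: AnnealSchedule,
    n_attempts: int,
    current_energy: float,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Run one insertion phase in place on ``torsions``; returns (energy, n accepted)."""
    accepted = 0
    n_windows = window_starts.shape[0]
    if n_attempts > 1:
        decay = (schedule.t_end / schedule.t_start) ** (1.0 / (n_attempts - 1))
    else:
        decay = 1.0
    temperature = schedule.t_start
    for _ in range(n_attempts):
        wi = rng.integers(n_windows)
        cands = cand_torsions[wi]
        frag = cands[rng.integers(len(cands))]
        start = window_starts[wi] - 1
        old = torsions[start : start + k].copy()
        torsions[start : start + k] = frag
        new_energy = score(Conformation(torsions=torsions), codes, weights)
        if metropolis_accept(new_energy - current_energy, temperature, rng):
            current_energy = new_energy
            accepted += 1
        else:
            torsions[start : start + k] = old
        temperature *= decay
    return current_energy, accepted


def run_protocol(
    lib9: FragmentLibrary,
    lib3: FragmentLibrary,
    ss: SecondaryStructure,
    weights: ScoreWeights | None = None,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
) -> Decoy:
    """Full two-phase assembly: 9-mer insertions then 3-mer refinement.

    Fully reproducible from ``seed``: a fresh PCG64 stream drives window
    and candidate choice and Metropolis draws.
    """
    weights = weights or ScoreWeights()
    schedule = schedule or AnnealSchedule()
    L = len(ss)
    if lib9.seq_len != L or lib3.seq_len != L:
        raise ValueError(
            f"library lengths ({lib9.seq_len}, {lib3.seq_len}) do not match SS length {L}"
        )
    codes = ss_codes(ss)
    rng = np.random.default_rng(seed)
    conf = extended_chain(L)
    torsions = conf.torsions.copy()
    energy = score(Conformation(torsions=torsions), codes, weights)

    accepted = []
    for lib, n_attempts in ((lib9, schedule.attempts_9mer), (lib3, schedule.attempts_3mer)):
        starts = np.array(lib.window_indices())
        cand_torsions = [
            [c.torsions() for c in lib.windows[idx].candidates] for idx in starts
        ]
        energy, acc = _phase(
            torsions, cand_torsions, starts, lib.k, codes, weights, schedule,
            n_attempts, energy, rng,
        )
        accepted.append(acc)

    final = Conformation(torsions=torsions)
    return Decoy(
        conformation=final,
        score=score(final, codes, weights),
        seed=seed,
        accepted_9mer=accepted[0],
        accepted_3mer=accepted[1],
    )


def generate_decoys(
    n: int,
    base_seed: int,
    lib9: FragmentLibrary,
    lib3: FragmentLibrary,
    ss: SecondaryStructure,
    weights: ScoreWeights | None = None,
    schedule: AnnealSchedule | None = None,
) -> list[Decoy]:
    """n independent decoys; decoy i uses seed base_seed + i (order-independent)."""
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    return [
        run_protocol(lib9, lib3, ss, weights=weights, schedule=schedule, seed=base_seed + i)
        for i in range(n)
    ]
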