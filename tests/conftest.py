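import numpy as np
import pytest

from fragcard.io import (
    FragmentCandidate,
    FragmentLibrary,
    FragmentWindow,
    ResidueRecord,
    SecondaryStructure,
)


def make_candidate(torsions, start=1, source="1xyz", chain="A", ss="L", extra=""):
    """Candidate from an iterable of (phi, psi, omega); ss may be a string of len k."""
    torsions = np.atleast_2d(np.asarray(torsions, dtype=float))
    k = torsions.shape[0]
    ss_str = ss * k if len(ss) == 1 else ss
    return FragmentCandidate(
        records=tuple(
            ResidueRecord(
                source_id=source,
                chain=chain,
                resseq=start + j,
                aa="A",
                ss=ss_str[j],
                phi=torsions[j, 0],
                psi=torsions[j, 1],
                omega=torsions[j, 2],
                extra=extra,
            )
            for j in range(k)
        )
    )


def make_library(k, seq_len, candidates_per_window, torsion_fn=None):
    """Uniform library; torsion_fn(window, rank) -> (k, 3) torsions (default helix-ish)."""
    if torsion_fn is None:
        def torsion_fn(w, r):
            return np.tile([-57.0 + r, -47.0 - r, 180.0], (k, 1))
    windows = {}
    for w in range(1, seq_len - k + 2):
        cands = [
            make_candidate(torsion_fn(w, r), start=w)
            for r in range(candidates_per_window)
        ]
        windows[w] = FragmentWindow(index=w, candidates=cands)
    return FragmentLibrary(k=k, seq_len=seq_len, windows=windows)


@pytest.fixture
def helix_ss30():
    return SecondaryStructure("CC" + "H" * 12 + "CC" + "H" * 12 + "CC")


@pytest.fixture
def mixed_ss():
    return SecondaryStructure("HHHHEEEECC")


def brute_force_rmsd(mobile, reference, grid_step_deg=20.0):
    """Independent minimal-RMSD oracle: Euler-angle grid search + Nelder-Mead refine.

    For a fixed rotation, the optimal translation aligns centroids, so the
    search is over rotations only.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)

    def cost(euler):
        R = Rotation.from_euler("zyx", euler, degrees=True).as_matrix()
        d = mc @ R.T - rc
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    best = None
    grid = np.arange(-180.0, 180.0, grid_step_deg)
    half = np.arange(-90.0, 90.1, grid_step_deg)
    for a in grid:
        for b in half:
            for c in grid:
                v = cost((a, b, c))
                if best is None or v < best[0]:
                    best = (v, (a, b, c))
    res = minimize(cost, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    return min(best[0], float(res.fun))
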