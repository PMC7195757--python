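"""Readers and writers for fragment files, secondary-structure inputs, and backbone PDB.

The fragment-file dialect is a minimal superset of the classic Rosetta
fragment format: a ``position: <p> neighbors: <n>`` header per window,
followed by ``n`` candidates of ``k`` whitespace-separated record lines
each, candidates separated by blank lines.  Record fields, in order:
``source_id chain resseq aa ss phi psi omega [extra...]``.  Unrecognized
trailing columns are preserved verbatim so that files survive a
parse/write round trip.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResidueRecord",
    "FragmentCandidate",
    "FragmentWindow",
    "FragmentLibrary",
    "SecondaryStructure",
    "BackboneStructure",
    "FragmentFormatError",
    "parse_fragment_file",
    "write_fragment_file",
    "read_ss",
    "parse_backbone_pdb",
    "write_backbone_pdb",
]

SS3_ALPHABET = frozenset("HEC")

#: DSSP 8-state -> 3-state reduction (helix-like to H, extended/bridge to E, rest coil)
DSSP8_TO_3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "-": "C", " ": "C", "P": "C",
}


class FragmentFormatError(ValueError):
    """Raised when a fragment file or SS input violates the expected format."""


def wrap_angle(x: float) -> float:
    """Normalize an angle in degrees to the interval (-180, 180]."""
    x = float(x) % 360.0
    if x > 180.0:
        x -= 360.0
    if x == -180.0:
        x = 180.0
    return x


@dataclass(frozen=True)
class ResidueRecord:
    """One line of a fragment file: a residue of a template structure."""

    source_id: str
    chain: str
    resseq: int
    aa: str
    ss: str  # H, E or L (fragment-file coil letter)
    phi: float
    psi: float
    omega: float
    extra: str = ""

    def __post_init__(self) -> None:
        if self.ss not in ("H", "E", "L"):
            raise FragmentFormatError(f"record ss must be H/E/L, got {self.ss!r}")
        for name in ("phi", "psi", "omega"):
            if not np.isfinite(getattr(self, name)):
                raise FragmentFormatError(f"non-finite {name} in record for {self.source_id}")


@dataclass(frozen=True)
class FragmentCandidate:
    """An ordered run of k residue records excised from one source structure."""

    records: tuple[ResidueRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise FragmentFormatError("empty candidate")
        first = self.records[0]
        for i, r in enumerate(self.records):
            if r.source_id != first.source_id or r.chain != first.chain:
                raise FragmentFormatError(
                    f"candidate mixes sources: {first.source_id}/{first.chain} vs "
                    f"{r.source_id}/{r.chain}"
                )
            if r.resseq != first.resseq + i:
                raise FragmentFormatError(
                    f"non-consecutive resseq in candidate from {first.source_id}: "
                    f"expected {first.resseq + i}, got {r.resseq}"
                )

    @property
    def k(self) -> int:
        return len(self.records)

    def torsions(self) -> np.ndarray:
        """(k, 3) array of (phi, psi, omega) in degrees."""
        return np.array([[r.phi, r.psi, r.omega] for r in self.records], dtype=float)

    def ss_string(self) -> str:
        """3-state SS of the records with the coil letter normalized to C."""
        return "".join("C" if r.ss == "L" else r.ss for r in self.records)


@dataclass
class FragmentWindow:
    """Rank-ordered candidate list for one target window (file order = picker rank)."""

    index: int
    candidates: list[FragmentCandidate]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise FragmentFormatError(f"window {self.index} has no candidates")

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


@dataclass
class FragmentLibrary:
    """Per-window fragment candidates for one target sequence.

    Window indices are 1-based and run 1 ... L - k + 1.
    """

    k: int
    seq_len: int
    windows: dict[int, FragmentWindow] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k not in (3, 9):
            raise ValueError(f"fragment length must be 3 or 9, got {self.k}")
        expected = set(range(1, self.seq_len - self.k + 2))
        if set(self.windows) != expected:
            raise FragmentFormatError(
                f"window indices {sorted(self.windows)} do not cover 1..{self.seq_len - self.k + 1}"
            )
        for idx, w in self.windows.items():
            if w.index != idx:
                raise FragmentFormatError(f"window keyed {idx} carries index {w.index}")
            for c in w.candidates:
                if c.k != self.k:
                    raise FragmentFormatError(
                        f"window {idx}: candidate of length {c.k} in a {self.k}-mer library"
                    )

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def total_candidates(self) -> int:
        return sum(w.n_candidates for w in self.windows.values())

    def window_indices(self) -> list[int]:
        return sorted(self.windows)

    def copy(self) -> "FragmentLibrary":
        return FragmentLibrary(
            k=self.k,
            seq_len=self.seq_len,
            windows={
                i: FragmentWindow(index=i, candidates=list(w.candidates))
                for i, w in self.windows.items()
            },
        )


@dataclass(frozen=True)
class SecondaryStructure:
    """3-state secondary structure string over {H, E, C}."""

    symbols: str

    def __post_init__(self) -> None:
        for i, s in enumerate(self.symbols):
            if s not in SS3_ALPHABET:
                raise ValueError(f"invalid SS symbol {s!r} at position {i + 1}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __getitem__(self, i):
        return self.symbols[i]


@dataclass
class BackboneStructure:
    """Backbone N/CA/C coordinates (Angstrom) for residues 1..L."""

    n: np.ndarray   # (L, 3)
    ca: np.ndarray  # (L, 3)
    c: np.ndarray   # (L, 3)
    resnames: list[str] | None = None

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if not (self.n.shape == self.ca.shape == self.c.shape) or self.n.ndim != 2 or self.n.shape[1] != 3:
            raise ValueError("n, ca, c must all be (L, 3) arrays")

    @property
    def length(self) -> int:
        return self.n.shape[0]

    def backbone_atoms(self, start: int = 1, stop: int | None = None) -> np.ndarray:
        """(3m, 3) array of N, CA, C atoms for residues start..stop (1-based, inclusive)."""
        stop = self.length if stop is None else stop
        sl = slice(start - 1, stop)
        out = np.empty((3 * (stop - start + 1), 3))
        out[0::3] = self.n[sl]
        out[1::3] = self.ca[sl]
        out[2::3] = self.c[sl]
        return out

    def validate_native(self) -> None:
        """Check consecutive CA-CA distances lie in the physical 2.5-4.5 A band."""
        d = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        bad = np.where((d < 2.5) | (d > 4.5))[0]
        if bad.size:
            raise ValueError(
                f"CA-CA distance out of [2.5, 4.5] A between residues {bad[0] + 1} and {bad[0] + 2}: "
                f"{d[bad[0]]:.2f} A"
            )


# ---------------------------------------------------------------------------
# Fragment files

_POSITION_RE = re.compile(r"^\s*position:\s*(\d+)\s+neighbors:\s*(\d+)\s*$")


def _parse_record(line: str, lineno: int) -> ResidueRecord:
    parts = line.split()
    if len(parts) < 8:
        raise FragmentFormatError(f"line {lineno}: expected >= 8 fields, got {len(parts)}")
    source_id, chain, resseq_s, aa, ss = parts[:5]
    try:
        resseq = int(resseq_s)
        phi, psi, omega = (float(parts[i]) for i in (5, 6, 7))
    except ValueError as exc:
        raise FragmentFormatError(f"line {lineno}: non-numeric field ({exc})") from None
    if ss == "C":
        ss = "L"
    return ResidueRecord(
        source_id=source_id,
        chain=chain,
        resseq=resseq,
        aa=aa,
        ss=ss,
        phi=wrap_angle(phi),
        psi=wrap_angle(psi),
        omega=wrap_angle(omega),
        extra=" ".join(parts[8:]),
    )


def parse_fragment_file(text: str) -> FragmentLibrary:
    """Parse fragment-file text into a :class:`FragmentLibrary`.

    The fragment length k is inferred from the lines-per-candidate and must
    be constant across the file; candidate order within a window is
    preserved (it encodes the picker's rank).
    """
    windows: dict[int, FragmentWindow] = {}
    k: int | None = None

    # Split into per-window chunks on position headers.
    header_hits: list[tuple[int, int, int]] = []  # (line index, position, neighbors)
    lines = text.splitlines()
    for i, line in enumerate(lines):
        m = _POSITION_RE.match(line)
        if m:
            header_hits.append((i, int(m.group(1)), int(m.group(2))))
        elif line.strip() and line.lstrip().startswith("position:"):
            raise FragmentFormatError(f"line {i + 1}: malformed position header: {line!r}")
    if not header_hits:
        raise FragmentFormatError("no 'position:' headers found")

    for h, (start, pos, neighbors) in enumerate(header_hits):
        if pos in windows:
            raise FragmentFormatError(f"duplicate window header for position {pos}")
        end = header_hits[h + 1][0] if h + 1 < len(header_hits) else len(lines)
        candidates: list[FragmentCandidate] = []
        block: list[ResidueRecord] = []
        for j in range(start + 1, end):
            line = lines[j]
            if line.strip():
                block.append(_parse_record(line, j + 1))
            elif block:
                candidates.append(FragmentCandidate(records=tuple(block)))
                block = []
        if block:
            candidates.append(FragmentCandidate(records=tuple(block)))
        if not candidates:
            raise FragmentFormatError(f"window {pos}: no candidates")
        for c in candidates:
            if k is None:
                k = c.k
            elif c.k != k:
                raise FragmentFormatError(
                    f"window {pos}: candidate of length {c.k}, expected {k}"
                )
        if neighbors != len(candidates):
            raise FragmentFormatError(
                f"window {pos}: header declares {neighbors} neighbors, found {len(candidates)}"
            )
        windows[pos] = FragmentWindow(index=pos, candidates=candidates)

    assert k is not None
    seq_len = max(windows) + k - 1
    return FragmentLibrary(k=k, seq_len=seq_len, windows=windows)


def write_fragment_file(lib: FragmentLibrary) -> str:
    """Serialize a library to fragment-file text; inverse of :func:`parse_fragment_file`."""
    out: list[str] = []
    for idx in lib.window_indices():
        w = lib.windows[idx]
        out.append(f"position: {w.index:12d} neighbors: {w.n_candidates:12d}")
        out.append("")
        for c in w.candidates:
            for r in c.records:
                line = (
                    f" {r.source_id} {r.chain} {r.resseq:5d} {r.aa} {r.ss} "
                    f"{r.phi:9.3f} {r.psi:9.3f} {r.omega:9.3f}"
                )
                if r.extra:
                    line += f" {r.extra}"
                out.append(line)
            out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Secondary structure

def _read_ss_plain(text: str) -> str:
    sym = text.strip()
    if "\n" in sym:
        raise ValueError("plain SS input must be a single line")
    out = []
    for i, s in enumerate(sym):
        s = s.upper()
        if s == "L":  # coil synonym used inside fragment files
            s = "C"
        if s not in SS3_ALPHABET:
            raise ValueError(f"invalid SS symbol {sym[i]!r} at position {i + 1}")
        out.append(s)
    return "".join(out)


def _read_ss_ss2(text: str) -> str:
    """PSIPRED vertical format: rows ``index aa ss pC pH pE`` after a comment line.

    The 3-state call is the argmax of the three confidence columns; ties
    break H > E > C.
    """
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) < 6:
            raise ValueError(f"ss2 line {lineno}: expected 6 columns, got {len(parts)}")
        try:
            p_c, p_h, p_e = float(parts[3]), float(parts[4]), float(parts[5])
        except ValueError:
            raise ValueError(f"ss2 line {lineno}: non-numeric confidence column") from None
        # tie-break H > E > C
        best = max((p_h, "H"), (p_e, "E"), (p_c, "C"), key=lambda t: (t[0], "CEH".index(t[1])))
        out.append(best[1])
    if not out:
        raise ValueError("ss2 input contains no data rows")
    return "".join(out)


def _read_ss_dssp8(text: str) -> str:
    sym = text.strip()
    out = []
    for i, s in enumerate(sym):
        try:
            out.append(DSSP8_TO_3[s.upper()])
        except KeyError:
            raise ValueError(f"invalid DSSP symbol {s!r} at position {i + 1}") from None
    return "".join(out)


def read_ss(text: str, format: str = "plain") -> SecondaryStructure:
    """Read a secondary-structure annotation and normalize it to 3 states.

    Parameters
    ----------
    text:
        Input text: a single H/E/C(/L) line (``plain``), a PSIPRED .ss2
        file (``ss2``), or a DSSP 8-state string (``dssp8``; mapped
        H,G,I -> H; E,B -> E; everything else -> C).
    """
    readers = {"plain": _read_ss_plain, "ss2": _read_ss_ss2, "dssp8": _read_ss_dssp8}
    try:
        reader = readers[format]
    except KeyError:
        raise ValueError(f"unknown SS format {format!r}; expected one of {sorted(readers)}") from None
    return SecondaryStructure(symbols=reader(text))


# ---------------------------------------------------------------------------
# PDB backbone

_BACKBONE_ATOMS = ("N", "CA", "C")


def parse_backbone_pdb(text: str, chain: str | None = None) -> BackboneStructure:
    """Read N/CA/C coordinates from PDB ATOM records.

    Residues are renumbered 1..L in order of appearance.  Alternate
    locations resolve to the highest occupancy, then first seen.  A residue
    missing any backbone atom is an error.
    """
    # residue key -> atom name -> (occupancy, order, xyz)
    residues: dict[tuple[str, int, str], dict[str, tuple[float, int, np.ndarray]]] = {}
    resnames: dict[tuple[str, int, str], str] = {}
    order = 0
    for line in text.splitlines():
        if not line.startswith("ATOM"):
            continue
        atom_name = line[12:16].strip()
        if atom_name not in _BACKBONE_ATOMS:
            continue
        ch = line[21]
        if chain is not None and ch != chain:
            continue
        resseq = int(line[22:26])
        icode = line[26]
        key = (ch, resseq, icode)
        try:
            occ = float(line[54:60])
        except ValueError:
            occ = 1.0
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        slot = residues.setdefault(key, {})
        prev = slot.get(atom_name)
        if prev is None or occ > prev[0]:
            if prev is None:
                slot[atom_name] = (occ, order, xyz)
            else:
                slot[atom_name] = (occ, prev[1], xyz)  # keep original appearance order
        resnames.setdefault(key, line[17:20].strip())
        order += 1

    if not residues:
        raise ValueError(
            "no backbone ATOM records found"
            + (f" for chain {chain!r}" if chain is not None else "")
        )

    keys = sorted(residues, key=lambda k: min(v[1] for v in residues[k].values()))
    missing = [k for k in keys if set(residues[k]) != set(_BACKBONE_ATOMS)]
    if missing:
        pretty = ", ".join(f"{ch}:{rs}{ic.strip()}" for ch, rs, ic in missing)
        raise ValueError(f"residues missing backbone atoms: {pretty}")

    n = np.array([residues[k]["N"][2] for k in keys])
    ca = np.array([residues[k]["CA"][2] for k in keys])
    c = np.array([residues[k]["C"][2] for k in keys])
    return BackboneStructure(n=n, ca=ca, c=c, resnames=[resnames[k] for k in keys])


def write_backbone_pdb(structure: BackboneStructure, chain: str = "A") -> str:
    """Write backbone N/CA/C atoms as PDB ATOM records (fixed 3-decimal precision)."""
    lines = []
    serial = 1
    for i in range(structure.length):
        resname = structure.resnames[i] if structure.resnames else "ALA"
        for atom_name, xyz in zip(_BACKBONE_ATOMS, (structure.n[i], structure.ca[i], structure.c[i])):
            name_field = f" {atom_name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name_field}{' '}{resname:>3s} {chain}{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
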