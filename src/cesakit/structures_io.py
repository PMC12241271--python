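"""Structures, trajectories, and nonbonded-parameter I/O.

Coordinates are Å throughout the package.  The canonical trajectory dialect
is a multi-model PDB file (one ``MODEL``/``ENDMDL`` block per frame over a
fixed topology); a directory of per-frame PDB files is accepted as a
secondary dialect.  No periodic-boundary imaging is applied anywhere:
inputs are assumed wrapped and whole.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "NonbondedParams",
    "PDBParseError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "read_nonbonded_params",
    "select_atoms",
    "kabsch_rmsd",
    "infer_element",
    "infer_hydrogen_bonds",
]

# Residue-name tables used to classify molecules.  Glucan residues follow
# the common pyranose codes plus the generic "GLC" used by our generator.
PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
GLUCAN_RESNAMES = {"GLC", "BGC", "GLB", "4GB", "CBI"}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}

# Two-letter element exceptions checked against the leading characters of
# the stripped atom name.  "CA"/"CB"... deliberately absent (alpha carbon).
_TWO_LETTER_ELEMENTS = ("CL", "BR", "FE", "ZN", "MG", "MN")


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be parsed; names the offending line."""


def infer_element(atom_name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Rule: first alphabetic character of the stripped name, with a small
    two-letter exception table (halogens/metals).  Good enough for the
    C/H/N/O/S chemistry this package analyzes.
    """
    name = atom_name.strip().upper()
    for two in _TWO_LETTER_ELEMENTS:
        if name.startswith(two):
            return two.capitalize()
    for ch in name:
        if ch.isalpha():
            return ch
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass(frozen=True)
class Atom:
    """A single atom of the fixed topology."""

    serial: int
    name: str
    element: str
    is_hydrogen: bool
    residue_index: int
    residue_name: str
    chain_id: str
    position: tuple[float, float, float] = (math.nan, math.nan, math.nan)

    def __post_init__(self):
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if (self.element.upper() == "H") != self.is_hydrogen:
            raise ValueError(
                f"element {self.element!r} inconsistent with is_hydrogen="
                f"{self.is_hydrogen} for atom {self.name!r}"
            )


def _molecule_class(residue_name: str) -> str:
    if residue_name in PROTEIN_RESNAMES:
        return "protein"
    if residue_name in GLUCAN_RESNAMES:
        return "glucan"
    return "other"


@dataclass
class Topology:
    """Ordered atom list with explicit bonds and per-atom molecule class."""

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) out of range for {n} atoms")
        self.molecule_class = [_molecule_class(a.residue_name) for a in self.atoms]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def bonded_to(self, index: int) -> list[int]:
        out = []
        for i, j in self.bonds:
            if i == index:
                out.append(j)
            elif j == index:
                out.append(i)
        return out

    def residues(self) -> list[tuple[str, int, str]]:
        """Distinct (chain_id, residue_index, residue_name) in atom order."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_index), a.residue_name)
        return [(c, r, n) for (c, r), n in seen.items()]

    def atom_indices(self, chain_id: str | None = None,
                     residue_index: int | None = None) -> list[int]:
        out = []
        for i, a in enumerate(self.atoms):
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if residue_index is not None and a.residue_index != residue_index:
                continue
            out.append(i)
        return out


@dataclass
class Frame:
    """One trajectory frame: an N×3 Å coordinate array over the topology."""

    index: int
    time: float  # ns
    coordinates: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an N×3 array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]
    frame_spacing: float = 1.0  # ns between successive frames

    def __post_init__(self):
        n = self.topology.n_atoms
        idx = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {f.index} has {f.coordinates.shape[0]} atoms, "
                    f"topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class NonbondedParams:
    """Per-atom charge (e), Lennard-Jones sigma (Å) and epsilon (kcal/mol)."""

    charge: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self):
        self.charge = np.asarray(self.charge, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be non-negative")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(
            f"malformed ATOM/HETATM record at line {lineno}: {line.rstrip()!r}"
        ) from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = infer_element(name)
    element = element.capitalize()
    return Atom(
        serial=serial, name=name, element=element,
        is_hydrogen=element.upper() == "H",
        residue_index=resid, residue_name=resname, chain_id=chain,
        position=(x, y, z),
    )


def _read_pdb_models(path: Path) -> list[tuple[list[Atom], np.ndarray]]:
    models: list[tuple[list[Atom], np.ndarray]] = []
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model = True
                atoms, coords = [], []
            elif rec == "ENDMDL":
                in_model = False
                models.append((atoms, np.asarray(coords, dtype=float)))
                atoms, coords = [], []
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                atoms.append(atom)
                coords.append(atom.position)
    if atoms:  # trailing model without ENDMDL, or un-modelled file
        models.append((atoms, np.asarray(coords, dtype=float)))
    if not models:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")
    return models


def read_structure(path: str | Path) -> tuple[Topology, Frame]:
    """Read a PDB file; return its topology and first-model coordinates.

    Multi-model files are accepted: only the first model is returned and a
    warning is emitted.  Hydrogen-to-heavy bonds are inferred geometrically
    (each H attached to its nearest heavy atom within 1.4 Å).
    """
    path = Path(path)
    models = _read_pdb_models(path)
    if len(models) > 1:
        warnings.warn(
            f"{path} contains {len(models)} models; returning the first",
            stacklevel=2,
        )
    atoms, coords = models[0]
    topo = Topology(atoms=atoms)
    frame = Frame(index=0, time=0.0, coordinates=coords)
    topo.bonds = infer_hydrogen_bonds(topo, frame)
    topo = Topology(atoms=atoms, bonds=topo.bonds)
    return topo, frame


def infer_hydrogen_bonds(topology: Topology, frame: Frame,
                         max_dist: float = 1.4) -> list[tuple[int, int]]:
    """Attach each hydrogen to its nearest heavy atom within ``max_dist`` Å.

    Used when a structure file carries no explicit bond list; only H-heavy
    bonds are needed downstream (donor pairing, C-H enumeration).
    """
    xyz = frame.coordinates
    heavy = [i for i, a in enumerate(topology.atoms) if not a.is_hydrogen]
    bonds: list[tuple[int, int]] = []
    if not heavy:
        return bonds
    heavy_xyz = xyz[heavy]
    for i, a in enumerate(topology.atoms):
        if not a.is_hydrogen:
            continue
        d = np.linalg.norm(heavy_xyz - xyz[i], axis=1)
        j = int(np.argmin(d))
        if d[j] > max_dist:
            raise ValueError(
                f"hydrogen {a.name} (serial {a.serial}) has no heavy atom "
                f"within {max_dist} Å"
            )
        bonds.append((heavy[j], i))
    return bonds


def read_trajectory(path: str | Path, topology: Topology | None = None,
                    frame_spacing: float = 1.0) -> Trajectory:
    """Read a trajectory from a multi-model PDB or a directory of PDB files.

    Frames are ordered by model number (multi-model file) or by sorted
    filename (directory dialect).  Every frame must match the topology's
    atom count.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".pdb")
        if not files:
            raise FileNotFoundError(f"no .pdb files in directory {path}")
        models = []
        for p in files:
            models.extend(_read_pdb_models(p))
    else:
        models = _read_pdb_models(path)
    if topology is None:
        topology = Topology(atoms=models[0][0])
        topology.bonds = infer_hydrogen_bonds(
            topology, Frame(index=0, time=0.0, coordinates=models[0][1])
        )
    frames = []
    for k, (atoms, coords) in enumerate(models):
        if len(atoms) != topology.n_atoms:
            raise ValueError(
                f"frame {k} has {len(atoms)} atoms, expected {topology.n_atoms}"
            )
        frames.append(Frame(index=k, time=k * frame_spacing, coordinates=coords))
    return Trajectory(topology=topology, frames=frames,
                      frame_spacing=frame_spacing)


def _write_model(fh, topology: Topology, coords: np.ndarray) -> None:
    for i, atom in enumerate(topology.atoms):
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        record = ("ATOM  " if _molecule_class(atom.residue_name) == "protein"
                  else "HETATM")
        fh.write(
            f"{record}{i + 1:5d} {name:<4s} {atom.residue_name:>3s} "
            f"{atom.chain_id}{atom.residue_index:4d}    "
            f"{coords[i, 0]:8.3f}{coords[i, 1]:8.3f}{coords[i, 2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {atom.element.upper():>2s}\n"
        )


def write_structure(path: str | Path, topology: Topology, frame: Frame) -> None:
    """Write a single-model PDB file (coordinates printed at %.3f Å)."""
    with open(path, "w") as fh:
        _write_model(fh, topology, frame.coordinates)
        fh.write("END\n")


def write_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    """Write a multi-model PDB trajectory."""
    with open(path, "w") as fh:
        for k, frame in enumerate(trajectory.frames, start=1):
            fh.write(f"MODEL {k:8d}\n")
            _write_model(fh, trajectory.topology, frame.coordinates)
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Nonbonded parameter tables
# ---------------------------------------------------------------------------

def read_nonbonded_params(path: str | Path, topology: Topology) -> NonbondedParams:
    """Read a delimited parameter table and align it to the topology.

    Expected columns: chain, residue_index, atom_name, charge, sigma,
    epsilon (tab- or comma-separated, with header).  Every topology atom
    must be matched exactly once.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    required = {"chain", "residue_index", "atom_name", "charge", "sigma", "epsilon"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"parameter table missing columns: {sorted(missing_cols)}")
    table: dict[tuple[str, int, str], tuple[float, float, float]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.chain), int(row.residue_index), str(row.atom_name))
        if key in table:
            raise ValueError(f"duplicate parameter row for atom {key}")
        table[key] = (float(row.charge), float(row.sigma), float(row.epsilon))
    charge = np.empty(topology.n_atoms)
    sigma = np.empty(topology.n_atoms)
    epsilon = np.empty(topology.n_atoms)
    unmatched = []
    for i, a in enumerate(topology.atoms):
        key = (a.chain_id, a.residue_index, a.name)
        if key not in table:
            unmatched.append(key)
            continue
        charge[i], sigma[i], epsilon[i] = table[key]
    if unmatched:
        raise ValueError(f"parameter table does not cover atoms: {unmatched[:10]}"
                         + ("..." if len(unmatched) > 10 else ""))
    return NonbondedParams(charge=charge, sigma=sigma, epsilon=epsilon)


def write_nonbonded_params(path: str | Path, topology: Topology,
                           params: NonbondedParams) -> None:
    import pandas as pd

    rows = [
        {
            "chain": a.chain_id, "residue_index": a.residue_index,
            "atom_name": a.name, "charge": params.charge[i],
            "sigma": params.sigma[i], "epsilon": params.epsilon[i],
        }
        for i, a in enumerate(topology.atoms)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Atom selection mini-language
# ---------------------------------------------------------------------------

def _tokenize(selector: str) -> list[str]:
    return selector.replace("(", " ( ").replace(")", " ) ").split()


class _SelParser:
    """Recursive-descent parser for the selection mini-language.

    Grammar: expr := term ("or" term)*; term := factor ("and" factor)*;
    factor := "not" factor | "(" expr ")" | primitive.
    Primitives: chain X | resid N[-M] | resname XXX | heavy | hydrogen |
    sidechain | backbone | protein | glucan | all.
    """

    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.topo = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise ValueError(f"unexpected token {self.peek()!r} in selection")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise ValueError("unbalanced parentheses in selection")
            return mask
        return self.primitive()

    def primitive(self) -> np.ndarray:
        tok = self.take().lower()
        atoms = self.topo.atoms
        n = len(atoms)
        if tok == "chain":
            val = self.take()
            return np.array([a.chain_id == val for a in atoms])
        if tok == "resid":
            val = self.take()
            if "-" in val[1:]:  # range N-M (leading '-' would be a sign)
                a_str, b_str = val[1:].split("-", 1)
                lo, hi = int(val[0] + a_str), int(b_str)
            else:
                lo = hi = int(val)
            return np.array([lo <= a.residue_index <= hi for a in atoms])
        if tok == "resname":
            val = self.take().upper()
            return np.array([a.residue_name == val for a in atoms])
        if tok == "heavy":
            return np.array([not a.is_hydrogen for a in atoms])
        if tok == "hydrogen":
            return np.array([a.is_hydrogen for a in atoms])
        if tok == "backbone":
            return np.array([a.name in BACKBONE_NAMES for a in atoms])
        if tok == "sidechain":
            # beyond backbone N/CA/C/O (and backbone H); includes CB
            return np.array([a.name not in BACKBONE_NAMES for a in atoms])
        if tok == "protein":
            return np.array([c == "protein" for c in self.topo.molecule_class])
        if tok == "glucan":
            return np.array([c == "glucan" for c in self.topo.molecule_class])
        if tok == "all":
            return np.ones(n, dtype=bool)
        raise ValueError(f"unknown selector token {tok!r}")


def select_atoms(topology: Topology, selector: str) -> list[int]:
    """Evaluate a selection expression; return sorted atom indices."""
    mask = _SelParser(_tokenize(selector), topology).parse()
    return [int(i) for i in np.flatnonzero(mask)]


# ---------------------------------------------------------------------------
# Kabsch superposition RMSD
# ---------------------------------------------------------------------------

def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Optimal-superposition RMSD between two matched coordinate sets.

    The rotation minimizing the squared deviation after centering is found
    by SVD (Kabsch), with the determinant correction that excludes improper
    rotations.  Degenerate (collinear or fewer than 3 points) inputs raise.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matched M×3 arrays")
    m = A.shape[0]
    if m < 3:
        raise ValueError("at least 3 points are required")
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    if np.linalg.matrix_rank(A0, tol=1e-8) < 2 or np.linalg.matrix_rank(B0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinate set")
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ A0.T).T - B0
    return float(np.sqrt((diff ** 2).sum() / m))
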