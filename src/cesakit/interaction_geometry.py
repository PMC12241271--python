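"""Geometric hydrogen-bond and CH-π stacking detection.

Hydrogen bonds use the classic two-criterion rule: donor-acceptor heavy
atom distance within a cutoff (default 3.5 Å) and donor-hydrogen-acceptor
angle at least a minimum (default 120°).

CH-π stacking of a sugar C-H on an aromatic ring face uses three criteria:
carbon-to-ring-centroid distance (default ≤ 4.5 Å), in-plane offset of the
carbon's projection from the centroid (default ≤ 2.0 Å), and the angle
between the C→H bond vector and the ring normal (default ≤ 40°, taking the
smaller of θ and 180° − θ since the normal's sign is arbitrary).  Only
glucan C-H donors against protein aromatic rings are scanned; tryptophan is
evaluated over both its five- and six-membered rings.

Occupancies are ANY-combination per frame: a frame counts once no matter
how many donor/acceptor or C-H/ring combinations qualify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structures_io import BACKBONE_NAMES, Frame, Topology, Trajectory

__all__ = [
    "HBondCriteria",
    "CHPiCriteria",
    "AromaticRing",
    "RING_ATOM_NAMES",
    "find_donors_acceptors",
    "hbond_frame",
    "hbond_time",
    "ring_plane",
    "chpi_frame",
    "chpi_time",
]


@dataclass(frozen=True)
class HBondCriteria:
    donor_acceptor_max: float = 3.5  # Å
    dha_angle_min: float = 120.0     # degrees

    def __post_init__(self):
        if self.donor_acceptor_max <= 0:
            raise ValueError("donor_acceptor_max must be positive")
        if not 0.0 <= self.dha_angle_min <= 180.0:
            raise ValueError("dha_angle_min must be within [0, 180] degrees")


@dataclass(frozen=True)
class CHPiCriteria:
    c_centroid_max: float = 4.5      # Å
    proj_offset_max: float = 2.0     # Å
    ch_normal_angle_max: float = 40.0  # degrees

    def __post_init__(self):
        if min(self.c_centroid_max, self.proj_offset_max,
               self.ch_normal_angle_max) <= 0:
            raise ValueError("all CH-π criteria must be positive")
        if self.ch_normal_angle_max > 90.0:
            raise ValueError("ch_normal_angle_max must be ≤ 90°")


# Ring membership per aromatic residue; Trp contributes two π systems.
# His is listed here as a π ring; its chemistry class elsewhere (cationic)
# is an independent table.
RING_ATOM_NAMES: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}


@dataclass
class AromaticRing:
    residue_chain: str
    residue_index: int
    residue_name: str
    member_names: list[str]
    centroid: np.ndarray
    normal: np.ndarray  # unit, sign-free


def find_donors_acceptors(topology: Topology, atom_indices: list[int] | None = None
                          ) -> tuple[list[tuple[int, int]], list[int]]:
    """Enumerate H-bond donors (D, H) pairs and acceptor atoms A.

    Donors are N/O heavy atoms with a bonded hydrogen; acceptors are all
    N/O heavy atoms.  Restricted to ``atom_indices`` when given.  A
    hydroxyl oxygen is both donor and acceptor.
    """
    allowed = set(atom_indices) if atom_indices is not None else None
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    h_partner: dict[int, int] = {}
    for i, j in topology.bonds:
        ai, aj = topology.atoms[i], topology.atoms[j]
        if ai.is_hydrogen and not aj.is_hydrogen:
            h_partner[i] = j
        elif aj.is_hydrogen and not ai.is_hydrogen:
            h_partner[j] = i
    for i, a in enumerate(topology.atoms):
        if a.is_hydrogen and i not in h_partner:
            raise ValueError(
                f"hydrogen {a.name} (serial {a.serial}) has no bonded heavy atom"
            )
    for i, a in enumerate(topology.atoms):
        if allowed is not None and i not in allowed:
            continue
        if a.is_hydrogen or a.element.upper() not in ("N", "O"):
            continue
        acceptors.append(i)
        for h, heavy in h_partner.items():
            if heavy == i:
                donors.append((i, h))
    return donors, acceptors


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("coincident atoms give a zero-length vector")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def hbond_frame(d_xyz: np.ndarray, h_xyz: np.ndarray, a_xyz: np.ndarray,
                criteria: HBondCriteria = HBondCriteria()) -> bool:
    """Two-criterion hydrogen-bond test for a (D, H, A) triple."""
    d_xyz, h_xyz, a_xyz = (np.asarray(p, dtype=float) for p in (d_xyz, h_xyz, a_xyz))
    da = float(np.linalg.norm(a_xyz - d_xyz))
    if da == 0.0:
        raise ValueError("donor and acceptor atoms are coincident")
    if da > criteria.donor_acceptor_max:
        return False
    angle = _angle_deg(d_xyz - h_xyz, a_xyz - h_xyz)
    return angle >= criteria.dha_angle_min


def _sidechain_indices(topology: Topology, chain: str, resid: int) -> list[int]:
    return [i for i in topology.atom_indices(chain_id=chain, residue_index=resid)
            if topology.atoms[i].name not in BACKBONE_NAMES]


def hbond_time(trajectory: Trajectory, residue: tuple[str, int],
               glucan_chain: str,
               criteria: HBondCriteria = HBondCriteria(),
               stride: int = 1) -> float:
    """Percent of frames with ANY side-chain/glucan hydrogen bond.

    Both directions are scanned: residue side-chain donors against glucan
    acceptors, and glucan donors against residue side-chain acceptors.
    """
    topo = trajectory.topology
    res_atoms = _sidechain_indices(topo, *residue)
    glu_atoms = topo.atom_indices(chain_id=glucan_chain)
    res_don, res_acc = find_donors_acceptors(topo, res_atoms)
    glu_don, glu_acc = find_donors_acceptors(topo, glu_atoms)
    triples = [(d, h, a) for (d, h) in res_don for a in glu_acc] + \
              [(d, h, a) for (d, h) in glu_don for a in res_acc]
    if not triples:
        return 0.0
    frames = trajectory.frames[::stride]
    hits = 0
    for fr in frames:
        xyz = fr.coordinates
        for d, h, a in triples:
            if hbond_frame(xyz[d], xyz[h], xyz[a], criteria):
                hits += 1
                break
    return 100.0 * hits / len(frames)


def ring_plane(ring_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit least-squares plane normal of a ring atom set.

    The normal is the smallest-variance principal direction of the centered
    coordinates (SVD); its sign is arbitrary.  Collinear input raises.
    """
    xyz = np.asarray(ring_xyz, dtype=float)
    if xyz.ndim != 2 or xyz.shape[0] < 3:
        raise ValueError("a ring needs at least 3 atoms")
    centroid = xyz.mean(axis=0)
    centered = xyz - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("ring atoms are collinear; plane undefined")
    normal = vt[2]
    return centroid, normal / np.linalg.norm(normal)


def aromatic_rings(topology: Topology, frame: Frame, chain: str, resid: int
                   ) -> list[AromaticRing]:
    """AromaticRing objects for one residue in one frame ([] if non-aromatic)."""
    atoms = topology.atom_indices(chain_id=chain, residue_index=resid)
    if not atoms:
        raise ValueError(f"no atoms for residue {resid} in chain {chain}")
    resname = topology.atoms[atoms[0]].residue_name
    rings = []
    for member_names in RING_ATOM_NAMES.get(resname, []):
        idx = [i for i in atoms if topology.atoms[i].name in member_names]
        if len(idx) != len(member_names):
            continue  # incomplete ring in the structure
        centroid, normal = ring_plane(frame.coordinates[idx])
        rings.append(AromaticRing(
            residue_chain=chain, residue_index=resid, residue_name=resname,
            member_names=member_names, centroid=centroid, normal=normal,
        ))
    return rings


def chpi_frame(c_xyz: np.ndarray, h_xyz: np.ndarray, ring: AromaticRing,
               criteria: CHPiCriteria = CHPiCriteria()) -> bool:
    """Three-criterion CH-π test for one glucan C-H against one ring."""
    c_xyz = np.asarray(c_xyz, dtype=float)
    h_xyz = np.asarray(h_xyz, dtype=float)
    to_c = c_xyz - ring.centroid
    if np.linalg.norm(to_c) > criteria.c_centroid_max:
        return False
    # projection of C onto the ring plane, offset from the centroid
    offset = to_c - np.dot(to_c, ring.normal) * ring.normal
    if np.linalg.norm(offset) > criteria.proj_offset_max:
        return False
    angle = _angle_deg(h_xyz - c_xyz, ring.normal)
    angle = min(angle, 180.0 - angle)  # normal sign is arbitrary
    return angle <= criteria.ch_normal_angle_max


def _glucan_ch_pairs(topology: Topology, glucan_chain: str
                     ) -> list[tuple[int, int]]:
    glu = set(topology.atom_indices(chain_id=glucan_chain))
    pairs = []
    for i, j in topology.bonds:
        if i in glu and j in glu:
            ai, aj = topology.atoms[i], topology.atoms[j]
            if ai.element.upper() == "C" and aj.is_hydrogen:
                pairs.append((i, j))
            elif aj.element.upper() == "C" and ai.is_hydrogen:
                pairs.append((j, i))
    return pairs


def chpi_time(trajectory: Trajectory, residue: tuple[str, int],
              glucan_chain: str,
              criteria: CHPiCriteria = CHPiCriteria(),
              stride: int = 1) -> float:
    """Percent of frames with ANY glucan C-H stacked on the residue's rings.

    Non-aromatic residues are defined as 0% (with a warning rather than an
    error, so whole-table sweeps stay convenient).
    """
    topo = trajectory.topology
    chain, resid = residue
    atoms = topo.atom_indices(chain_id=chain, residue_index=resid)
    if not atoms:
        raise ValueError(f"no atoms for residue {resid} in chain {chain}")
    resname = topo.atoms[atoms[0]].residue_name
    if resname not in RING_ATOM_NAMES:
        warnings.warn(
            f"residue {resname}{resid} is not aromatic; CH-π time defined as 0%",
            stacklevel=2,
        )
        return 0.0
    ch_pairs = _glucan_ch_pairs(topo, glucan_chain)
    frames = trajectory.frames[::stride]
    hits = 0
    for fr in frames:
        rings = aromatic_rings(topo, fr, chain, resid)
        xyz = fr.coordinates
        found = False
        for ring in rings:
            for c, h in ch_pairs:
                if chpi_frame(xyz[c], xyz[h], ring, criteria):
                    found = True
                    break
            if found:
                break
        hits += found
    return 100.0 * hits / len(frames)
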