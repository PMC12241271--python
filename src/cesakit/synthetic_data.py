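"""Deterministic, seeded generators for every input class of the pipeline.

The trajectory generator places idealized residue stubs (chemically correct
side-chain atom names, bonds, and hydrogens) around a linear β-1,4 glucan
with chair-ring geometry, and toggles each residue between four placement
states per frame — detached, contact-only, hydrogen-bonding, CH-π stacked —
on deterministic interleaved masks, so designed occupancies are met EXACTLY
(not statistically).  All generators are pure functions of their spec and
seed; there is no global random state.

What the toy system emulates: the distance/angle geometry of residue-glucan
contacts in a glucan translocation channel.  What it does not emulate:
forces, dynamics, solvent, or realistic packing — frames are independent
placements, not physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scattering import DetectorImage, QCalibration, q_map
from .phenotype_stats import CellPolygon, ComplementationTable
from .structures_io import (
    Atom,
    Frame,
    NonbondedParams,
    Topology,
    Trajectory,
)

__all__ = [
    "PairSpec",
    "TrajectorySpec",
    "ScatterSpec",
    "CountsSpec",
    "SynthTrajectory",
    "synth_trajectory",
    "synth_detector_image",
    "synth_counts",
    "synth_polygons",
    "exact_occupancy_mask",
    "synth_contact_reference_table",
]


# ---------------------------------------------------------------------------
# Exact-occupancy masks
# ---------------------------------------------------------------------------

def exact_occupancy_mask(n_frames: int, percent: float) -> np.ndarray:
    """Deterministic boolean mask with exactly percent% True frames.

    Frames are spread by Bresenham interleaving, so runs are as even as the
    target allows.  The requested percentage must be representable with
    ``n_frames`` frames.
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError("occupancy percent must be within [0, 100]")
    k_exact = percent * n_frames / 100.0
    k = round(k_exact)
    if abs(k - k_exact) > 1e-9:
        raise ValueError(
            f"occupancy {percent}% is not exactly representable with "
            f"{n_frames} frames"
        )
    f = np.arange(n_frames + 1)
    return np.diff((f * k) // n_frames).astype(bool)


def _sub_mask(parent: np.ndarray, k: int) -> np.ndarray:
    """Mask with k True frames interleaved among the True frames of parent."""
    idx = np.flatnonzero(parent)
    child = np.zeros_like(parent)
    if k:
        sel = exact_occupancy_mask(idx.size, 100.0 * k / idx.size)
        child[idx[sel]] = True
    return child


# ---------------------------------------------------------------------------
# Residue and glucose templates (local coordinates, Å)
# ---------------------------------------------------------------------------

# Each template is oriented with its "reach" atom at the origin and the
# rest of the residue extending toward +y (away from the glucan).  Donor
# templates carry the donor hydrogen at reach + (0, -0.95, 0) so that a
# translation alone produces a collinear D-H···A geometry.
_T = {
    "SER": dict(
        atoms=[("OG", "O", (0, 0, 0)), ("HG", "H", (0, -0.95, 0)),
               ("CB", "C", (0, 1.43, 0)), ("CA", "C", (0.83, 2.70, 0)),
               ("N", "N", (-0.37, 3.50, 0)), ("C", "C", (2.13, 3.40, 0)),
               ("O", "O", (2.73, 4.47, 0))],
        bonds=[("OG", "HG"), ("CB", "OG"), ("CA", "CB"), ("CA", "N"),
               ("CA", "C"), ("C", "O")],
        reach="OG", hbond_mode="donor",
    ),
    "ARG": dict(
        atoms=[("NH1", "N", (0, 0, 0)), ("HH11", "H", (0, -0.95, 0)),
               ("HH12", "H", (0.93, 0.25, 0)), ("CZ", "C", (-0.55, 1.21, 0)),
               ("NH2", "N", (-1.88, 1.05, 0)), ("HH21", "H", (-2.45, 0.28, 0)),
               ("NE", "N", (-0.10, 2.46, 0)), ("HE", "H", (0.83, 2.66, 0)),
               ("CD", "C", (-1.05, 3.51, 0)), ("CG", "C", (-0.25, 4.76, 0)),
               ("CB", "C", (-1.05, 6.01, 0)), ("CA", "C", (-0.20, 7.26, 0)),
               ("N", "N", (-1.50, 7.86, 0)), ("C", "C", (1.05, 8.01, 0)),
               ("O", "O", (1.60, 9.11, 0))],
        bonds=[("NH1", "HH11"), ("NH1", "HH12"), ("CZ", "NH1"), ("CZ", "NH2"),
               ("NH2", "HH21"), ("CZ", "NE"), ("NE", "HE"), ("NE", "CD"),
               ("CD", "CG"), ("CG", "CB"), ("CB", "CA"), ("CA", "N"),
               ("CA", "C"), ("C", "O")],
        reach="NH1", hbond_mode="donor",
    ),
    "GLU": dict(
        atoms=[("OE1", "O", (0, 0, 0)), ("CD", "C", (0.63, 1.10, 0)),
               ("OE2", "O", (1.95, 1.10, 0)), ("CG", "C", (-0.10, 2.35, 0)),
               ("CB", "C", (0.70, 3.60, 0)), ("CA", "C", (-0.10, 4.85, 0)),
               ("N", "N", (-1.40, 5.45, 0)), ("C", "C", (1.15, 5.60, 0)),
               ("O", "O", (1.15, 6.83, 0))],
        bonds=[("CD", "OE1"), ("CD", "OE2"), ("CG", "CD"), ("CB", "CG"),
               ("CA", "CB"), ("CA", "N"), ("CA", "C"), ("C", "O")],
        reach="OE1", hbond_mode="acceptor",
    ),
    "PHE": dict(
        atoms=[("CZ", "C", (0, 0, 0)), ("CE1", "C", (1.204, 0.695, 0)),
               ("CE2", "C", (-1.204, 0.695, 0)), ("CD1", "C", (1.204, 2.085, 0)),
               ("CD2", "C", (-1.204, 2.085, 0)), ("CG", "C", (0, 2.78, 0)),
               ("CB", "C", (0, 4.28, 0)), ("CA", "C", (0.83, 5.55, 0)),
               ("N", "N", (-0.40, 6.30, 0)), ("C", "C", (2.10, 6.30, 0)),
               ("O", "O", (2.60, 7.40, 0))],
        bonds=[("CZ", "CE1"), ("CE1", "CD1"), ("CD1", "CG"), ("CG", "CD2"),
               ("CD2", "CE2"), ("CE2", "CZ"), ("CG", "CB"), ("CB", "CA"),
               ("CA", "N"), ("CA", "C"), ("C", "O")],
        reach="CZ", hbond_mode=None, ring_centroid_atoms=(
            "CZ", "CE1", "CE2", "CD1", "CD2", "CG"),
    ),
    "TRP": dict(
        atoms=[("CD2", "C", (0, 1.39, 0)), ("CE3", "C", (-1.204, 0.695, 0)),
               ("CZ3", "C", (-1.204, -0.695, 0)), ("CH2", "C", (0, -1.39, 0)),
               ("CZ2", "C", (1.204, -0.695, 0)), ("CE2", "C", (1.204, 0.695, 0)),
               ("CG", "C", (0.290, 2.749, 0)), ("CD1", "C", (1.672, 2.895, 0)),
               ("NE1", "N", (2.237, 1.625, 0)), ("HE1", "H", (3.166, 1.427, 0)),
               ("CB", "C", (-0.21, 4.10, 0)), ("CA", "C", (0.62, 5.37, 0)),
               ("N", "N", (-0.61, 6.12, 0)), ("C", "C", (1.89, 6.12, 0)),
               ("O", "O", (2.39, 7.22, 0))],
        bonds=[("CD2", "CE3"), ("CE3", "CZ3"), ("CZ3", "CH2"), ("CH2", "CZ2"),
               ("CZ2", "CE2"), ("CE2", "CD2"), ("CD2", "CG"), ("CG", "CD1"),
               ("CD1", "NE1"), ("NE1", "CE2"), ("NE1", "HE1"), ("CG", "CB"),
               ("CB", "CA"), ("CA", "N"), ("CA", "C"), ("C", "O")],
        reach="CH2", hbond_mode=None, ring_centroid_atoms=(
            "CD2", "CE3", "CZ3", "CH2", "CZ2", "CE2"),
    ),
    "LEU": dict(
        atoms=[("CD1", "C", (0, 0, 0)), ("HD11", "H", (0, -1.09, 0)),
               ("CG", "C", (0.51, 1.40, 0)), ("CD2", "C", (1.95, 1.55, 0)),
               ("CB", "C", (-0.29, 2.70, 0)), ("CA", "C", (0.51, 3.99, 0)),
               ("N", "N", (-0.45, 5.00, 0)), ("C", "C", (1.80, 4.60, 0)),
               ("O", "O", (2.30, 5.70, 0))],
        bonds=[("CD1", "HD11"), ("CG", "CD1"), ("CG", "CD2"), ("CB", "CG"),
               ("CA", "CB"), ("CA", "N"), ("CA", "C"), ("C", "O")],
        reach="CD1", hbond_mode=None,
    ),
}

_GLUCOSE_SPACING = 6.0  # Å between successive glucose-unit centers


def _glucose_atoms(unit: int, terminal: bool) -> tuple[list, list]:
    """Idealized chair β-d-glucose unit centered at x = unit·spacing.

    Equatorial hydroxyls O2/O3 (+O6 on the exocyclic arm) carry hydrogens;
    O4 is the glycosidic bridge except on the terminal (unit 0) end, where
    it is a hydroxyl.  Axial ring hydrogens point along ±z.
    """
    r, pz = 1.5, 0.25
    ring = {
        "C1": (r, 0.0, pz), "C2": (r / 2, r * 0.866, -pz),
        "C3": (-r / 2, r * 0.866, pz), "C4": (-r, 0.0, -pz),
        "C5": (-r / 2, -r * 0.866, pz), "O5": (r / 2, -r * 0.866, -pz),
    }
    atoms = []
    bonds = []
    x0 = unit * _GLUCOSE_SPACING
    pos = {}

    def add(name, element, p):
        pos[name] = np.asarray(p, dtype=float)
        atoms.append((name, element, (p[0] + x0, p[1], p[2])))

    for name, p in ring.items():
        add(name, name[0], p)
    # axial hydrogens, opposite the pucker displacement
    for cname in ("C1", "C2", "C3", "C4", "C5"):
        c = pos[cname]
        add("H" + cname[1], "H", (c[0], c[1], c[2] - math.copysign(1.09, c[2])))
        bonds.append((cname, "H" + cname[1]))
    # equatorial hydroxyls on C2 and C3
    for cname, ang in (("C2", 60.0), ("C3", 120.0)):
        d = np.array([math.cos(math.radians(ang)), math.sin(math.radians(ang)), 0.0])
        c = pos[cname]
        oname = "O" + cname[1]
        add(oname, "O", tuple(c + 1.43 * d))
        add("H" + oname, "H", tuple(c + (1.43 + 0.95) * d))
        bonds.extend([(cname, oname), (oname, "H" + oname)])
    # O4: glycosidic bridge, hydroxyl only on the terminal end
    c4 = pos["C4"]
    add("O4", "O", tuple(c4 + np.array([-1.43, 0.0, 0.0])))
    bonds.append(("C4", "O4"))
    if terminal:
        add("HO4", "H", tuple(c4 + np.array([-2.38, 0.0, 0.0])))
        bonds.append(("O4", "HO4"))
    # exocyclic C6-O6-HO6 arm
    c5 = pos["C5"]
    add("C6", "C", tuple(c5 + np.array([-0.51, -0.88, 0.95])))
    add("H61", "H", tuple(pos["C6"] + np.array([-0.9, 0.0, 0.6])))
    add("O6", "O", tuple(pos["C6"] + np.array([0.0, -1.20, 0.80])))
    add("HO6", "H", tuple(pos["O6"] + np.array([0.0, -0.95, 0.0])))
    bonds.extend([("C5", "C6"), ("C6", "H61"), ("C6", "O6"), ("O6", "HO6")])
    # intra-ring bonds
    ring_names = ["C1", "C2", "C3", "C4", "C5", "O5"]
    bonds.extend(zip(ring_names, ring_names[1:] + ring_names[:1]))
    return atoms, bonds


# ---------------------------------------------------------------------------
# Trajectory generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairSpec:
    """Designed occupancies (%) for one residue-glucan pair."""

    residue_name: str
    contact_pct: float = 0.0
    hbond_pct: float = 0.0
    chpi_pct: float = 0.0


@dataclass(frozen=True)
class TrajectorySpec:
    pairs: tuple[PairSpec, ...]
    n_frames: int = 200
    frame_spacing: float = 0.5  # ns
    glucan_length: int = 0      # 0 → one unit per pair (min 2)
    protein_chain: str = "A"
    glucan_chain: str = "G"
    seed: int = 0


@dataclass
class SynthTrajectory:
    trajectory: Trajectory
    params: NonbondedParams
    truth: pd.DataFrame
    masks: dict[tuple[str, int], dict[str, np.ndarray]]


_ELEMENT_NB = {  # charge (e), sigma (Å), epsilon (kcal/mol) by element
    "C": (0.15, 3.40, 0.10),
    "O": (-0.45, 3.00, 0.17),
    "N": (-0.40, 3.25, 0.17),
    "H": (0.10, 2.00, 0.02),
}


def _validate_pair(p: PairSpec, n_frames: int) -> None:
    tmpl = _T.get(p.residue_name)
    if tmpl is None:
        raise ValueError(f"no template for residue {p.residue_name!r}; "
                         f"available: {sorted(_T)}")
    for pct in (p.contact_pct, p.hbond_pct, p.chpi_pct):
        if not 0 <= pct <= 100:
            raise ValueError("occupancies must be within [0, 100]")
    if p.hbond_pct + p.chpi_pct > p.contact_pct + 1e-9:
        raise ValueError(
            f"{p.residue_name}: hbond% + chpi% must not exceed contact% "
            "(hydrogen-bonded and stacked frames are contact frames)"
        )
    if p.chpi_pct > 0 and "ring_centroid_atoms" not in tmpl:
        raise ValueError(f"{p.residue_name} is not aromatic; chpi% must be 0")
    if p.hbond_pct > 0 and tmpl["hbond_mode"] is None:
        raise ValueError(f"{p.residue_name} has no side-chain donor/acceptor; "
                         "hbond% must be 0")


def synth_trajectory(spec: TrajectorySpec) -> SynthTrajectory:
    """Generate a toy trajectory with exactly the designed occupancies.

    Residue i of the protein chain is paired with glucose unit i of the
    glucan chain; per frame each residue is rigidly translated into one of
    four states (detached / contact-only / hydrogen-bonding / CH-π
    stacked) following deterministic interleaved masks.  The truth table
    records the masks, the designed percentages, and mean interaction
    energies computed by a plain double-loop sum (12 Å cutoff) independent
    of the analysis modules.
    """
    n = spec.n_frames
    if n < 1:
        raise ValueError("n_frames must be positive")
    for p in spec.pairs:
        _validate_pair(p, n)
    n_units = max(spec.glucan_length or 0, len(spec.pairs), 2)

    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    name_index: dict[tuple[str, int, str], int] = {}
    base_xyz: list[tuple[float, float, float]] = []
    serial = 1

    def add_atom(name, element, resname, chain, resid, p):
        nonlocal serial
        atoms.append(Atom(
            serial=serial, name=name, element=element,
            is_hydrogen=element == "H", residue_index=resid,
            residue_name=resname, chain_id=chain, position=tuple(p),
        ))
        name_index[(chain, resid, name)] = len(atoms) - 1
        base_xyz.append(tuple(p))
        serial += 1

    # glucan chain, residue indices 1..n_units
    for u in range(n_units):
        ga, gb = _glucose_atoms(u, terminal=(u == 0))
        for aname, elem, p in ga:
            add_atom(aname, elem, "GLC", spec.glucan_chain, u + 1, p)
        for n1, n2 in gb:
            bonds.append((name_index[(spec.glucan_chain, u + 1, n1)],
                          name_index[(spec.glucan_chain, u + 1, n2)]))
    for u in range(n_units - 1):  # β-1,4 glycosidic bridges
        bonds.append((name_index[(spec.glucan_chain, u + 1, "C1")],
                      name_index[(spec.glucan_chain, u + 2, "O4")]))

    # residue stubs, residue indices 1..n_pairs, initially at the OFF anchor
    residue_atom_ranges: list[tuple[int, int]] = []
    for i, p in enumerate(spec.pairs):
        tmpl = _T[p.residue_name]
        start = len(atoms)
        for aname, elem, local in tmpl["atoms"]:
            add_atom(aname, elem, p.residue_name, spec.protein_chain, i + 1,
                     np.asarray(local, dtype=float))
        for n1, n2 in tmpl["bonds"]:
            bonds.append((name_index[(spec.protein_chain, i + 1, n1)],
                          name_index[(spec.protein_chain, i + 1, n2)]))
        residue_atom_ranges.append((start, len(atoms)))

    topology = Topology(atoms=atoms, bonds=bonds)
    base = np.asarray(base_xyz, dtype=float)

    # per-residue placement anchors relative to the paired glucose unit
    def glucan_atom_xyz(unit, name):
        return base[name_index[(spec.glucan_chain, unit, name)]]

    placements = []
    masks: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for i, p in enumerate(spec.pairs):
        tmpl = _T[p.residue_name]
        unit = i + 1
        o3 = glucan_atom_xyz(unit, "O3")
        c3 = glucan_atom_xyz(unit, "C3")
        reach_local = np.asarray(
            dict((a[0], a[2]) for a in tmpl["atoms"])[tmpl["reach"]], float)
        targets = {
            "off": o3 + np.array([0.0, 30.0, 0.0]),
            "contact": o3 + np.array([0.0, 4.6, 0.0]),
        }
        if tmpl["hbond_mode"] == "donor":
            targets["hbond"] = o3 + np.array([0.0, 2.8, 0.0])
        elif tmpl["hbond_mode"] == "acceptor":
            ho3 = glucan_atom_xyz(unit, "HO3")
            direction = (ho3 - o3) / np.linalg.norm(ho3 - o3)
            targets["hbond"] = o3 + 2.9 * direction
        if "ring_centroid_atoms" in tmpl:
            local = dict((a[0], np.asarray(a[2], float)) for a in tmpl["atoms"])
            centroid_local = np.mean(
                [local[nm] for nm in tmpl["ring_centroid_atoms"]], axis=0)
            targets["chpi"] = c3 + np.array([0.0, 0.0, -3.4])
            targets["chpi_anchor"] = centroid_local
        contact = exact_occupancy_mask(n, p.contact_pct)
        hbond = _sub_mask(contact, round(p.hbond_pct * n / 100.0))
        remaining = contact & ~hbond
        chpi = _sub_mask(remaining, round(p.chpi_pct * n / 100.0))
        masks[(spec.protein_chain, i + 1)] = {
            "contact": contact, "hbond": hbond, "chpi": chpi,
        }
        placements.append((residue_atom_ranges[i], reach_local, targets,
                           contact, hbond, chpi))

    frames = []
    for f in range(n):
        xyz = base.copy()
        for (start, stop), reach_local, targets, contact, hbond, chpi \
                in placements:
            if hbond[f]:
                shift = targets["hbond"] - reach_local
            elif chpi[f]:
                shift = targets["chpi"] - targets["chpi_anchor"]
            elif contact[f]:
                shift = targets["contact"] - reach_local
            else:
                shift = targets["off"] - reach_local
            xyz[start:stop] += shift
        frames.append(Frame(index=f, time=f * spec.frame_spacing,
                            coordinates=xyz))
    trajectory = Trajectory(topology=topology, frames=frames,
                            frame_spacing=spec.frame_spacing)

    # nonbonded parameters: per-element values, neutralized per residue
    charge = np.empty(len(atoms))
    sigma = np.empty(len(atoms))
    epsilon = np.empty(len(atoms))
    for k, a in enumerate(atoms):
        charge[k], sigma[k], epsilon[k] = _ELEMENT_NB[a.element.upper()]
    for chain, resid, _ in topology.residues():
        idx = topology.atom_indices(chain_id=chain, residue_index=resid)
        charge[idx] -= charge[idx].mean()
    params = NonbondedParams(charge=charge, sigma=sigma, epsilon=epsilon)

    # independent ground-truth energies: plain double loop, 12 Å cutoff
    rows = []
    glu_idx = topology.atom_indices(chain_id=spec.glucan_chain)
    for i, p in enumerate(spec.pairs):
        start, stop = residue_atom_ranges[i]
        e_coul = e_lj = 0.0
        for fr in frames:
            for a in range(start, stop):
                for b in glu_idx:
                    dx = fr.coordinates[a] - fr.coordinates[b]
                    r = math.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
                    if r > 12.0:
                        continue
                    e_coul += 332.0522 * charge[a] * charge[b] / r
                    s = 0.5 * (sigma[a] + sigma[b])
                    e = math.sqrt(epsilon[a] * epsilon[b])
                    sr6 = (s / r) ** 6
                    e_lj += 4.0 * e * (sr6 * sr6 - sr6)
        m = masks[(spec.protein_chain, i + 1)]
        rows.append({
            "residue_chain": spec.protein_chain, "residue_index": i + 1,
            "residue_name": p.residue_name, "glucan_chain": spec.glucan_chain,
            "contact_pct": p.contact_pct, "hbond_pct": p.hbond_pct,
            "chpi_pct": p.chpi_pct,
            "n_contact_frames": int(m["contact"].sum()),
            "mean_coulomb": e_coul / len(frames),
            "mean_lj": e_lj / len(frames),
        })
    truth = pd.DataFrame(rows)
    return SynthTrajectory(trajectory=trajectory, params=params,
                           truth=truth, masks=masks)


# ---------------------------------------------------------------------------
# Detector-image generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakModel:
    center_q: float          # Å⁻¹
    sigma_q: float           # Å⁻¹
    amplitude: float
    chi_fwhm: float | None = None  # degrees; None → isotropic ring


@dataclass(frozen=True)
class ScatterSpec:
    shape: tuple[int, int] = (256, 384)
    calibration: QCalibration = field(default_factory=QCalibration)
    peaks: tuple[PeakModel, ...] = (
        PeakModel(center_q=1.55, sigma_q=0.03, amplitude=100.0, chi_fwhm=30.0),
        PeakModel(center_q=1.15, sigma_q=0.04, amplitude=80.0, chi_fwhm=30.0),
    )
    amorphous: PeakModel = PeakModel(center_q=1.40, sigma_q=0.15, amplitude=20.0)
    starch_amplitude: float = 0.0   # optional isotropic peak at 1.45 Å⁻¹
    background: float = 2.0
    poisson_noise: bool = False
    giwaxs_scale: float = 1.0       # arbitrary intensity scale of the GIWAXS
    rocking_angles: tuple[float, ...] = (5.67, 6.44, 7.23)
    seed: int = 0


def _model_intensity(q: np.ndarray, chi: np.ndarray, spec: ScatterSpec
                     ) -> np.ndarray:
    out = np.full_like(q, float(spec.background))
    for pk in spec.peaks:
        radial = pk.amplitude * np.exp(-0.5 * ((q - pk.center_q) / pk.sigma_q) ** 2)
        if pk.chi_fwhm is not None:
            s = pk.chi_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            radial = radial * np.exp(-0.5 * (chi / s) ** 2)
        out += radial
    am = spec.amorphous
    out += am.amplitude * np.exp(-0.5 * ((q - am.center_q) / am.sigma_q) ** 2)
    if spec.starch_amplitude:
        out += spec.starch_amplitude * np.exp(-0.5 * ((q - 1.45) / 0.02) ** 2)
    return out


def synth_detector_image(spec: ScatterSpec
                         ) -> tuple[DetectorImage, list[DetectorImage]]:
    """Synthetic GIWAXS image plus one rocking-scan image per rocking angle.

    Intensity per pixel is the analytic peak model evaluated at that
    pixel's (q, χ); the orientation distribution is a Gaussian in χ
    centered on the vertical.  The GIWAXS image carries an arbitrary
    intensity scale (``giwaxs_scale``) so pole-figure stitching has a real
    scale to recover; rocking images are on the reference scale and expose
    the low-χ branch.  Poisson noise, when enabled, is seeded and
    deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    probe = DetectorImage(intensity=np.zeros(spec.shape),
                          calibration=spec.calibration)
    q, chi = q_map(probe)
    model = _model_intensity(q, chi, spec)

    def finish(raw: np.ndarray) -> np.ndarray:
        if spec.poisson_noise:
            return rng.poisson(np.clip(raw, 0.0, None)).astype(float)
        return raw

    giwaxs = DetectorImage(intensity=finish(model * spec.giwaxs_scale),
                           calibration=spec.calibration,
                           mask=probe.mask.copy())
    rocking = [
        DetectorImage(intensity=finish(model.copy()),
                      calibration=QCalibration(
                          wavelength=spec.calibration.wavelength,
                          distance=spec.calibration.distance,
                          beam_center=spec.calibration.beam_center,
                          pixel_size=spec.calibration.pixel_size,
                          incident_angle=ang),
                      mask=probe.mask.copy())
        for ang in spec.rocking_angles
    ]
    return giwaxs, rocking


# ---------------------------------------------------------------------------
# Counts and polygons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountsSpec:
    genotypes: tuple[tuple[str, float, int], ...]  # (name, rescue p, n lines)
    seed: int = 0


def synth_counts(spec: CountsSpec) -> ComplementationTable:
    """Binomial rescue counts per genotype, seeded and deterministic."""
    rng = np.random.default_rng(spec.seed)
    names, ks, ns = [], [], []
    for name, p, n in spec.genotypes:
        if not 0.0 <= p <= 1.0:
            raise ValueError("rescue probability must be within [0, 1]")
        names.append(name)
        ks.append(int(rng.binomial(n, p)))
        ns.append(n)
    return ComplementationTable(genotypes=names, n_rescued=np.array(ks),
                                n_total=np.array(ns))


def synth_polygons(n: int, elongation: float, seed: int = 0,
                   shape: str = "ellipse", n_vertices: int = 24,
                   noise: float = 0.02, scale: float = 20.0
                   ) -> list[CellPolygon]:
    """Noisy elongated cell outlines with known aspect ratio.

    ``shape='ellipse'`` gives ellipse-like polygons with semi-axes
    (elongation·scale, scale) and multiplicative radial noise;
    ``'rectangle'`` gives axis-aligned rectangles (noise ignored), whose
    circularity has the closed form 4π·ab/(2a+2b)².  Circularity decreases
    monotonically with elongation for either shape.
    """
    if elongation < 1.0:
        raise ValueError("elongation must be ≥ 1")
    rng = np.random.default_rng(seed)
    polys = []
    for _ in range(n):
        if shape == "rectangle":
            a, b = elongation * scale, scale
            v = np.array([[0, 0], [a, 0], [a, b], [0, b]], dtype=float)
        elif shape == "ellipse":
            t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
            radial = 1.0 + noise * rng.standard_normal(n_vertices)
            v = np.column_stack([elongation * scale * np.cos(t) * radial,
                                 scale * np.sin(t) * radial])
        else:
            raise ValueError(f"unknown shape {shape!r}")
        polys.append(CellPolygon(vertices=v))
    return polys


# ---------------------------------------------------------------------------
# Synthetic strong-contact reference table
# ---------------------------------------------------------------------------

# The 23 strong-contact residues of the moss CESA5 glucan channel, grouped
# by side-chain chemistry (3 cationic, 2 anionic, 3 polar-uncharged, 10
# aromatic, 5 non-polar aliphatic).
STRONG_CONTACT_RESIDUES: list[tuple[int, str]] = [
    (281, "ARG"), (292, "ARG"), (1068, "ARG"),
    (311, "GLU"), (321, "ASP"),
    (317, "SER"), (894, "SER"), (1003, "ASN"),
    (288, "PHE"), (314, "PHE"), (318, "TRP"), (861, "TYR"), (871, "TYR"),
    (897, "PHE"), (1013, "PHE"), (1017, "PHE"), (1018, "PHE"), (1021, "TRP"),
    (285, "LEU"), (900, "LEU"), (1014, "GLY"), (1062, "ILE"), (1064, "PRO"),
]


def synth_contact_reference_table(seed: int = 0, n_total: int = 82,
                                  n_chains: int = 3) -> pd.DataFrame:
    """SYNTHETIC per-residue×chain contact-time table for filter testing.

    A stand-in for the study's (non-deposited) per-residue contact table:
    the 23 strong-contact residue identities are the channel residues named
    in the study's results, while the remaining ``n_total - 23`` residues
    and ALL occupancy values are synthetic, drawn so that exactly the
    strong-contact set passes the ≥80%-on-≥2-chains filter.  Columns:
    residue_index, residue_name, chain, total_contact_time.
    """
    rng = np.random.default_rng(seed)
    strong = list(STRONG_CONTACT_RESIDUES)
    n_weak = n_total - len(strong)
    if n_weak < 0:
        raise ValueError("n_total smaller than the strong-contact set")
    weak_names = ["SER", "THR", "LEU", "VAL", "ALA", "GLN", "LYS", "MET",
                  "PHE", "TYR", "ASN", "ILE", "GLY", "HIS", "THR", "VAL"]
    used = {r for r, _ in strong}
    weak: list[tuple[int, str]] = []
    resid = 260
    while len(weak) < n_weak:
        if resid not in used:
            weak.append((resid, weak_names[len(weak) % len(weak_names)]))
        resid += 2
    rows = []
    chains = [chr(ord("A") + c) for c in range(n_chains)]
    for residx, resname in strong:
        # ≥ 2 chains at/above threshold; the third varies, some at boundary
        vals = [float(rng.uniform(80.0, 100.0)),
                float(rng.uniform(85.0, 100.0)),
                float(rng.uniform(5.0, 79.9))]
        if residx % 5 == 0:
            vals[0] = 80.0  # inclusive-threshold boundary cases
        rng.shuffle(vals)
        for ch, v in zip(chains, vals):
            rows.append({"residue_index": residx, "residue_name": resname,
                         "chain": ch, "total_contact_time": round(v, 1)})
    for residx, resname in weak:
        # at most one chain reaches the threshold
        vals = [float(rng.uniform(0.5, 79.9)) for _ in range(n_chains)]
        if residx % 7 == 0:
            vals[0] = float(rng.uniform(80.0, 100.0))
        rng.shuffle(vals)
        for ch, v in zip(chains, vals):
            rows.append({"residue_index": residx, "residue_name": resname,
                         "chain": ch, "total_contact_time": round(v, 1)})
    return pd.DataFrame(rows).sort_values(
        ["residue_index", "chain"]).reset_index(drop=True)
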