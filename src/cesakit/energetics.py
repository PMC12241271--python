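"""Linear-interaction-energy style nonbonded decomposition.

Per-frame Coulomb and Lennard-Jones interaction energies between a residue
and a glucan chain, summed over atom pairs within a plain truncation cutoff
(default 12.0 Å, i.e. 1.2 nm) with Lorentz-Berthelot combination rules.
This is a post-processing contact-energy metric, not a simulation energy:
no switching, no Ewald, no 1-4 scaling (the two groups are distinct
molecules).

Units: charges in elementary charge, distances in Å, energies in kcal/mol.
The Coulomb constant 332.0522 kcal·Å/(mol·e²) follows the convention of the
MD engines behind the common protein/carbohydrate force fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structures_io import BACKBONE_NAMES, Frame, NonbondedParams, Topology, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "EnergySummary",
    "pair_nonbonded",
    "residue_glucan_energy",
    "mean_interaction_energy",
]

COULOMB_CONSTANT = 332.0522  # kcal·Å/(mol·e²)


@dataclass
class EnergySummary:
    residue_chain: str
    residue_index: int
    glucan_chain: str
    mean_coulomb: float
    mean_lj: float
    mean_total: float
    coulomb_series: np.ndarray
    lj_series: np.ndarray
    total_series: np.ndarray


def pair_nonbonded(q_i: float, q_j: float, sigma_i: float, sigma_j: float,
                   eps_i: float, eps_j: float, r: float,
                   ke: float = COULOMB_CONSTANT) -> tuple[float, float]:
    """Coulomb and Lennard-Jones energy of one atom pair at distance r (Å).

    Lorentz-Berthelot: σ_ij arithmetic mean, ε_ij geometric mean.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    coulomb = ke * q_i * q_j / r
    sigma = 0.5 * (sigma_i + sigma_j)
    eps = np.sqrt(eps_i * eps_j)
    sr6 = (sigma / r) ** 6
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    return float(coulomb), float(lj)


def _group_indices(topology: Topology, chain: str,
                   resid: int | None, sidechain_only: bool) -> list[int]:
    idx = topology.atom_indices(chain_id=chain, residue_index=resid)
    if sidechain_only:
        idx = [i for i in idx if topology.atoms[i].name not in BACKBONE_NAMES]
    return idx


def residue_glucan_energy(frame: Frame, topology: Topology,
                          residue: tuple[str, int], glucan_chain: str,
                          params: NonbondedParams, cutoff: float = 12.0,
                          sidechain_only: bool = False,
                          ke: float = COULOMB_CONSTANT
                          ) -> tuple[float, float, float]:
    """(coulomb, lj, total) between a residue and a glucan chain, one frame.

    Whole-residue atoms (backbone included) enter by default; set
    ``sidechain_only`` to restrict.  Pairs beyond the cutoff are truncated.
    Pass ``cutoff=np.inf`` for the untruncated sum.
    """
    res_idx = _group_indices(topology, residue[0], residue[1], sidechain_only)
    glu_idx = topology.atom_indices(chain_id=glucan_chain)
    if not res_idx or not glu_idx:
        raise ValueError("empty atom group for energy computation")
    r = cdist(frame.coordinates[res_idx], frame.coordinates[glu_idx])
    if np.any(r == 0.0):
        raise ValueError("coincident atoms (r = 0) in energy computation")
    mask = r <= cutoff
    if not mask.any():
        return 0.0, 0.0, 0.0
    qi = params.charge[res_idx][:, None]
    qj = params.charge[glu_idx][None, :]
    si = params.sigma[res_idx][:, None]
    sj = params.sigma[glu_idx][None, :]
    ei = params.epsilon[res_idx][:, None]
    ej = params.epsilon[glu_idx][None, :]
    sigma = 0.5 * (si + sj)
    eps = np.sqrt(ei * ej)
    with np.errstate(divide="ignore", over="ignore"):
        coul = np.where(mask, ke * qi * qj / r, 0.0)
        sr6 = np.where(mask, (sigma / r) ** 6, 0.0)
        lj = np.where(mask, 4.0 * eps * (sr6 * sr6 - sr6), 0.0)
    c, l = float(coul.sum()), float(lj.sum())
    return c, l, c + l


def mean_interaction_energy(trajectory: Trajectory,
                            pairs: list[tuple[str, int, str]],
                            params: NonbondedParams, cutoff: float = 12.0,
                            sidechain_only: bool = False,
                            stride: int = 1) -> list[EnergySummary]:
    """Per-frame series and arithmetic means for each residue-glucan pair."""
    frames = trajectory.frames[::stride]
    if not frames:
        raise ValueError("trajectory has no frames")
    out = []
    for res_chain, res_idx, glu_chain in pairs:
        series = np.array([
            residue_glucan_energy(fr, trajectory.topology,
                                  (res_chain, res_idx), glu_chain,
                                  params, cutoff, sidechain_only)
            for fr in frames
        ])
        out.append(EnergySummary(
            residue_chain=res_chain, residue_index=res_idx,
            glucan_chain=glu_chain,
            mean_coulomb=float(series[:, 0].mean()),
            mean_lj=float(series[:, 1].mean()),
            mean_total=float(series[:, 2].mean()),
            coulomb_series=series[:, 0], lj_series=series[:, 1],
            total_series=series[:, 2],
        ))
    return out
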