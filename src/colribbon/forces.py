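"""Vectorised energy and force evaluation for rod systems.

The nonbonded interactions (screened electrostatics + Lennard-Jones) act
between all bead pairs except directly bonded neighbours within a rod.  Pair
candidates come either from a periodic k-d tree neighbour query (fast path,
with a skin so the list can be reused across steps) or from the full distance
matrix (brute-force reference path used by the equivalence tests).

The box is periodic in x and y (minimum-image convention) and bounded in z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import ElectrostaticParams, LJParams, SurfaceParams

__all__ = ["Box", "Topology", "EnergyBreakdown", "compute_energy_forces",
           "candidate_pairs_brute", "candidate_pairs_tree", "NeighborList"]


@dataclass(frozen=True)
class Box:
    """Simulation slab: periodic in x and y, reflecting walls in z."""

    lx: float
    ly: float
    lz: float

    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz])


@dataclass(frozen=True)
class Topology:
    """Bond and angle index lists plus per-rod stiffness values."""

    bonds: np.ndarray       # (M, 2) int
    angles: np.ndarray      # (K, 3) int
    bond_r0: float
    bond_k: float
    bend_k: float
    bead_radius: float

    @classmethod
    def from_rod_index(cls, rod_index: np.ndarray, bond_r0: float,
                       bond_k: float, bend_k: float, bead_radius: float
                       ) -> "Topology":
        """Beads of a rod are assumed stored contiguously, in backbone order."""
        rod_index = np.asarray(rod_index)
        bonds, angles = [], []
        n = len(rod_index)
        for i in range(n - 1):
            if rod_index[i] == rod_index[i + 1]:
                bonds.append((i, i + 1))
        for i in range(n - 2):
            if rod_index[i] == rod_index[i + 1] == rod_index[i + 2]:
                angles.append((i, i + 1, i + 2))
        return cls(
            bonds=np.array(bonds, dtype=np.intp).reshape(-1, 2),
            angles=np.array(angles, dtype=np.intp).reshape(-1, 3),
            bond_r0=bond_r0, bond_k=bond_k, bend_k=bend_k,
            bead_radius=bead_radius,
        )


@dataclass
class EnergyBreakdown:
    pair_dh: float
    pair_lj: float
    bond: float
    bend: float
    surface: float

    @property
    def total(self) -> float:
        return self.pair_dh + self.pair_lj + self.bond + self.bend + self.surface


def min_image(disp: np.ndarray, box: Box) -> np.ndarray:
    """Minimum-image displacement: wrap x and y, leave z untouched."""
    out = disp.copy()
    out[..., 0] -= box.lx * np.round(out[..., 0] / box.lx)
    out[..., 1] -= box.ly * np.round(out[..., 1] / box.ly)
    return out


def candidate_pairs_brute(positions: np.ndarray, box: Box, cutoff: float
                          ) -> np.ndarray:
    """All pairs within cutoff from the full O(N^2) distance matrix."""
    n = len(positions)
    ii, jj = np.triu_indices(n, k=1)
    d = min_image(positions[jj] - positions[ii], box)
    r = np.linalg.norm(d, axis=1)
    keep = r < cutoff
    return np.column_stack([ii[keep], jj[keep]])


def candidate_pairs_tree(positions: np.ndarray, box: Box, cutoff: float
                         ) -> np.ndarray:
    """Pairs within cutoff via a periodic k-d tree.

    z is handed to the tree with a period much larger than the slab so no
    spurious wrap-around pairs can occur across the z boundary.
    """
    if cutoff >= 0.5 * min(box.lx, box.ly):
        return candidate_pairs_brute(positions, box, cutoff)
    z_period = max(4.0 * box.lz, 8.0 * cutoff)
    wrapped = positions.copy()
    wrapped[:, 0] %= box.lx
    wrapped[:, 1] %= box.ly
    wrapped[:, 2] = np.clip(wrapped[:, 2], 0.0, None) + 0.25 * z_period
    tree = cKDTree(wrapped, boxsize=[box.lx, box.ly, z_period])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    return np.sort(pairs, axis=1)


class NeighborList:
    """Verlet list with a skin: rebuilt only after beads have moved far
    enough that a pair could have crossed the interaction cutoff."""

    def __init__(self, cutoff: float, skin: float = 0.9):
        self.cutoff = cutoff
        self.skin = skin
        self._pairs: np.ndarray | None = None
        self._ref_positions: np.ndarray | None = None

    def pairs(self, positions: np.ndarray, box: Box) -> np.ndarray:
        if self._pairs is not None:
            drift = np.abs(positions - self._ref_positions).max()
            if drift < 0.5 * self.skin:
                return self._pairs
        self._pairs = candidate_pairs_tree(positions, box, self.cutoff + self.skin)
        self._ref_positions = positions.copy()
        return self._pairs


def compute_energy_forces(
    positions: np.ndarray,
    charges: np.ndarray,
    topology: Topology,
    box: Box,
    es: ElectrostaticParams,
    lj: LJParams,
    surf: SurfaceParams,
    pairs: np.ndarray | None = None,
) -> tuple[EnergyBreakdown, np.ndarray]:
    """Total energy (kT) and per-bead forces (kT/nm).

    ``pairs`` may be a pre-computed candidate list (from a neighbour list);
    if None the brute-force path is used.  Directly bonded pairs are excluded
    from the nonbonded sums.  Coincident beads raise ValueError.
    """
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    n = len(positions)
    forces = np.zeros_like(positions)
    rmax = max(es.cutoff, lj.cutoff)

    if pairs is None:
        pairs = candidate_pairs_brute(positions, box, rmax)
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)

    # drop bonded neighbours (vectorised membership test on packed keys)
    if len(topology.bonds) and len(pairs):
        sb = np.sort(topology.bonds, axis=1)
        bond_keys = np.unique(sb[:, 0].astype(np.int64) * n + sb[:, 1])
        pair_keys = pairs[:, 0].astype(np.int64) * n + pairs[:, 1]
        pairs = pairs[~np.isin(pair_keys, bond_keys, assume_unique=False)]

    e_dh = e_lj = 0.0
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = min_image(positions[j] - positions[i], box)
        r = np.linalg.norm(d, axis=1)
        if np.any(r == 0.0):
            raise ValueError("overlapping beads at r = 0")
        inside = r < rmax
        i, j, d, r = i[inside], j[inside], d[inside], r[inside]
        rhat = d / r[:, None]
        fmag = np.zeros_like(r)  # force on j along rhat (positive = repulsive)

        qq = charges[i] * charges[j]
        m = (r < es.cutoff) & (qq != 0.0)
        if np.any(m):
            lD, lB, rc = es.debye_length, es.bjerrum_length, es.cutoff
            ex = np.exp(-r[m] / lD)
            shift = np.exp(-rc / lD) / rc
            e_dh = float(np.sum(lB * qq[m] * (ex / r[m] - shift)))
            fmag[m] += lB * qq[m] * ex * (1.0 / r[m] ** 2 + 1.0 / (lD * r[m]))

        m = r < lj.cutoff
        if np.any(m) and lj.epsilon > 0:
            s6 = (lj.sigma / r[m]) ** 6
            sc6 = (lj.sigma / lj.cutoff) ** 6
            e_lj = float(np.sum(4 * lj.epsilon * (s6 * s6 - s6)
                                - 4 * lj.epsilon * (sc6 * sc6 - sc6)))
            fmag[m] += 24 * lj.epsilon * (2 * s6 * s6 - s6) / r[m]

        fj = rhat * fmag[:, None]
        np.add.at(forces, j, fj)
        np.add.at(forces, i, -fj)

    # bonded stretch
    e_bond = 0.0
    if len(topology.bonds):
        a, b = topology.bonds[:, 0], topology.bonds[:, 1]
        d = min_image(positions[b] - positions[a], box)
        r = np.linalg.norm(d, axis=1)
        dr = r - topology.bond_r0
        e_bond = float(0.5 * topology.bond_k * np.sum(dr ** 2))
        fb = -(topology.bond_k * dr / r)[:, None] * d  # force on b
        np.add.at(forces, b, fb)
        np.add.at(forces, a, -fb)

    # bending about the straight configuration
    e_bend = 0.0
    if len(topology.angles) and topology.bend_k > 0:
        a, b, c = (topology.angles[:, k] for k in range(3))
        d1 = min_image(positions[b] - positions[a], box)
        d2 = min_image(positions[c] - positions[b], box)
        n1 = np.linalg.norm(d1, axis=1)
        n2 = np.linalg.norm(d2, axis=1)
        e1 = d1 / n1[:, None]
        e2 = d2 / n2[:, None]
        cosphi = np.clip(np.sum(e1 * e2, axis=1), -1.0, 1.0)
        phi = np.arccos(cosphi)
        e_bend = float(0.5 * topology.bend_k * np.sum(phi ** 2))
        sinphi = np.sqrt(np.clip(1.0 - cosphi ** 2, 0.0, None))
        # g = k * phi / sin(phi), finite limit k as phi -> 0
        small = sinphi < 1e-8
        g = np.where(small, topology.bend_k,
                     topology.bend_k * phi / np.where(small, 1.0, sinphi))
        # F = g * grad(cos phi)
        dcos_dd1 = (e2 - cosphi[:, None] * e1) / n1[:, None]
        dcos_dd2 = (e1 - cosphi[:, None] * e2) / n2[:, None]
        fa = -g[:, None] * dcos_dd1
        fc = g[:, None] * dcos_dd2
        np.add.at(forces, a, fa)
        np.add.at(forces, c, fc)
        np.add.at(forces, b, -(fa + fc))

    # substrate term
    e_surf = 0.0
    if surf.mode == "on":
        z = positions[:, 2]
        ez = np.exp(-z / surf.decay_length)
        e_surf = float(np.sum(-surf.strength * charges * ez))
        forces[:, 2] += -surf.strength * charges * ez / surf.decay_length
    return EnergyBreakdown(e_dh, e_lj, e_bond, e_bend, e_surf), forces
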