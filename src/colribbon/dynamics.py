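"""Overdamped Langevin (Brownian) dynamics of collagen-mimetic rods.

The system is a quasi-2D slab: beads interact above a charged substrate at
z = 0, with periodic boundaries in x and y and reflecting walls in z (at the
bead radius and at the top of the slab).  Integration is first-order
Euler-Maruyama,

    x <- x + (F / gamma) dt + sqrt(2 kT dt / gamma) * eta,

which is the standard scheme for an implicit-solvent bath with no inertia.
A pH protocol reassigns the discrete bead charges mid-run, driving the
disassembly (acidic) and reassembly (neutral) of the ribbon.

Units are reduced: lengths in nm, energies in kT at 300 K, friction gamma = 1
per bead by default, so the time unit is gamma nm^2 / kT and a free bead has
diffusion constant kT/gamma = 1 nm^2 per unit time.  No mapping to seconds is
attempted.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import forces as _forces
from .forces import Box, NeighborList, Topology, compute_energy_forces
from .model import (ChargedRod, ElectrostaticParams, LJParams, SurfaceParams,
                    assign_charges)

__all__ = ["SystemState", "SimParams", "PHProtocol", "Trajectory",
            "ModelParams", "build_ribbon_state", "free_gas_state", "step",
            "run_protocol", "write_xyz", "read_xyz", "write_hdf5"]

HULMES_ROWS = 5  # molecules per axial repeat column in the Hulmes stagger


@dataclass(frozen=True)
class ModelParams:
    """Bundle of interaction parameters handed to the integrator."""

    es: ElectrostaticParams
    lj: LJParams
    surf: SurfaceParams


@dataclass
class SystemState:
    """Positions, rod assignment and charges of every bead at one instant."""

    positions: np.ndarray          # (N, 3) nm
    rod_index: np.ndarray          # (N,) int
    charges: np.ndarray            # (N,) elementary charges
    box: Box
    template: ChargedRod
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.rod_index = np.asarray(self.rod_index, dtype=np.intp)
        self.charges = np.asarray(self.charges, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_rods(self) -> int:
        return len(np.unique(self.rod_index)) if self.n_beads else 0

    def topology(self) -> Topology:
        t = self.template
        return Topology.from_rod_index(
            self.rod_index, bond_r0=t.bead_spacing, bond_k=t.bond_stiffness,
            bend_k=t.bend_stiffness, bead_radius=0.5 * t.bead_diameter)

    def rod_slices(self) -> list[np.ndarray]:
        """Bead-index arrays per rod, in rod order."""
        return [np.flatnonzero(self.rod_index == r)
                for r in np.unique(self.rod_index)]

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.rod_index.copy(),
                           self.charges.copy(), self.box, self.template,
                           self.time)


@dataclass(frozen=True)
class SimParams:
    """Integrator parameters.  ``temperature`` rescales the unit thermal
    energy (300 K -> kT = 1); 0 gives noiseless gradient descent."""

    temperature: float = 300.0
    friction: float = 1.0
    dt: float = 2e-3
    n_steps: int = 1000
    seed: int = 0
    neighbor_skin: float = 0.9
    #: trust-region clamp on the per-bead step length (nm).  The 12-6
    #: excluded-volume core is stiff compared with any affordable dt, so rare
    #: deep compressions are clamped instead of ejecting beads; None disables
    #: clamping (the too-large-step guard then aborts the run).
    max_move: float | None = 0.1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")

    @property
    def kT(self) -> float:
        return self.temperature / 300.0


@dataclass(frozen=True)
class PHProtocol:
    """Ordered (time, pH) schedule; the first entry must be at time 0."""

    schedule: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.schedule]
        if not self.schedule or times[0] != 0.0:
            raise ValueError("protocol must start at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("protocol times must be strictly increasing")

    def pH_at(self, t: float) -> float:
        ph = self.schedule[0][1]
        for t0, p in self.schedule:
            if t >= t0:
                ph = p
        return ph


@dataclass
class Trajectory:
    frames: list[SystemState]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# State builders
# ---------------------------------------------------------------------------

def build_ribbon_state(
    n_fibrils: int,
    molecules_per_fibril: int,
    stagger: float,
    template: ChargedRod,
    box: Box | None = None,
    row_spacing: float | None = None,
    z0: float | None = None,
    pH: float = 7.4,
) -> SystemState:
    """Lay rods out in the staggered (Hulmes-type) ribbon arrangement.

    Within a fibril, molecule j starts at axial position j * stagger and
    occupies lateral row j mod 5 (or fewer rows when there are fewer
    molecules), so axial neighbours are offset by exactly ``stagger`` and a
    molecule and its fifth successor share a row separated by the gap
    5*stagger - length.  Fibrils are stacked side by side in y.  All rods lie
    flat on the substrate at z = bead radius.
    """
    if stagger <= 0:
        raise ValueError("stagger must be > 0")
    if n_fibrils < 0 or molecules_per_fibril < 0:
        raise ValueError("counts must be >= 0")
    d = template.bead_diameter
    b = template.bead_spacing
    L = template.length
    dy = row_spacing if row_spacing is not None else d
    z = z0 if z0 is not None else 0.5 * d
    rows = min(HULMES_ROWS, max(molecules_per_fibril, 1))

    n_mol = n_fibrils * molecules_per_fibril
    if n_mol and molecules_per_fibril > rows:
        same_row_gap = rows * stagger - L
        if same_row_gap <= 0:
            raise ValueError(
                "geometry cannot fit: same-row molecules overlap "
                f"(rows*stagger - length = {same_row_gap:.3g} nm <= 0)")

    x_extent = (molecules_per_fibril - 1) * stagger + L if n_mol else 0.0
    y_extent = (n_fibrils * rows) * dy if n_mol else 0.0
    if box is None:
        box = Box(lx=max(x_extent + 10 * d, 20 * d),
                  ly=max(y_extent + 10 * d, 20 * d),
                  lz=max(6 * d, 4.0))
    if n_mol and (x_extent > box.lx or y_extent > box.ly):
        raise ValueError("geometry cannot fit the box")

    rod_template = assign_charges(template, pH)
    q_rod = rod_template.charge_array()
    positions, rod_idx, charges = [], [], []
    mol = 0
    for f in range(n_fibrils):
        for j in range(molecules_per_fibril):
            row = j % rows
            x0 = j * stagger + 2 * d
            y = (f * rows + row) * dy + 2 * d
            xs = x0 + b * np.arange(template.n_beads)
            pos = np.column_stack([xs, np.full_like(xs, y), np.full_like(xs, z)])
            positions.append(pos)
            rod_idx.append(np.full(template.n_beads, mol, dtype=np.intp))
            charges.append(q_rod)
            mol += 1
    if not positions:
        return SystemState(np.zeros((0, 3)), np.zeros(0, dtype=np.intp),
                           np.zeros(0), box, rod_template)
    return SystemState(np.concatenate(positions), np.concatenate(rod_idx),
                       np.concatenate(charges), box, rod_template)


def free_gas_state(n_beads: int, box: Box, template: ChargedRod,
                   seed: int = 0, z_band: tuple[float, float] | None = None
                   ) -> SystemState:
    """Ideal-gas state of unconnected beads (one 'rod' id per bead); used for
    diffusion calibration, with all interactions off by construction of the
    model parameters."""
    rng = np.random.default_rng(seed)
    lo = z_band[0] if z_band else 0.5 * template.bead_diameter
    hi = z_band[1] if z_band else box.lz
    pos = np.column_stack([
        rng.uniform(0, box.lx, n_beads),
        rng.uniform(0, box.ly, n_beads),
        rng.uniform(lo, hi, n_beads),
    ])
    return SystemState(pos, np.arange(n_beads, dtype=np.intp),
                       np.zeros(n_beads), box, template)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

class TimestepError(RuntimeError):
    pass


def _apply_walls_and_wrap(positions: np.ndarray, box: Box, radius: float) -> None:
    """Reflect at z = radius and z = lz; wrap periodically in x, y. In place."""
    z = positions[:, 2]
    z[:] = np.where(z < radius, 2 * radius - z, z)
    z[:] = np.where(z > box.lz, 2 * box.lz - z, z)
    np.clip(z, radius, box.lz, out=z)  # guard pathological double reflections
    positions[:, 0] %= box.lx
    positions[:, 1] %= box.ly


def _advance_inplace(positions: np.ndarray, charges: np.ndarray,
                     topo: Topology, box: Box, params: SimParams,
                     model: ModelParams, rng: np.random.Generator,
                     pairs: np.ndarray | None, bead_diameter: float) -> None:
    """One in-place Euler-Maruyama update of the position array."""
    _, F = compute_energy_forces(positions, charges, topo, box,
                                 model.es, model.lj, model.surf, pairs=pairs)
    disp = F * (params.dt / params.friction)
    if params.kT > 0:
        noise_amp = np.sqrt(2.0 * params.kT * params.dt / params.friction)
        disp += noise_amp * rng.standard_normal(positions.shape)
    if params.max_move is not None and len(disp):
        norms = np.linalg.norm(disp, axis=1)
        over = norms > params.max_move
        if np.any(over):
            disp[over] *= (params.max_move / norms[over])[:, None]
    max_disp = float(np.abs(disp).max(initial=0.0))
    if max_disp > 0.5 * bead_diameter:
        raise TimestepError(
            f"timestep too large: max displacement {max_disp:.3g} nm exceeds "
            f"half a bead diameter")
    positions += disp
    _apply_walls_and_wrap(positions, box, topo.bead_radius)


def step(state: SystemState, params: SimParams, model: ModelParams,
         rng: np.random.Generator, nlist: NeighborList | None = None,
         topology: Topology | None = None) -> SystemState:
    """One Euler-Maruyama update; returns a new state.

    Aborts with TimestepError if any bead would move farther than half a
    bead diameter in a single step.
    """
    topo = topology if topology is not None else state.topology()
    pairs = None
    if nlist is not None:
        pairs = nlist.pairs(state.positions, state.box)
    new = state.copy()
    _advance_inplace(new.positions, new.charges, topo, new.box, params,
                     model, rng, pairs, state.template.bead_diameter)
    new.time = state.time + params.dt
    return new


def run_protocol(initial: SystemState, protocol: PHProtocol,
                 params: SimParams, model: ModelParams,
                 frame_stride: int = 500) -> Trajectory:
    """Integrate ``params.n_steps`` steps, reassigning charges at each pH
    switch; frames (including the initial state) stored every
    ``frame_stride`` steps.  Same seed and config give a bit-identical
    trajectory."""
    rng = np.random.default_rng(params.seed)
    rmax = max(model.es.cutoff, model.lj.cutoff)
    nlist = NeighborList(rmax, params.neighbor_skin)
    state = initial.copy()
    topo = state.topology()

    current_pH = protocol.pH_at(state.time)
    state = _set_pH(state, current_pH)
    frames = [state.copy()]
    switch_iter = [(t, p) for t, p in protocol.schedule if t > state.time]

    positions = state.positions  # integrated in place
    d = state.template.bead_diameter
    for k in range(params.n_steps):
        state.time = frames[0].time + k * params.dt
        while switch_iter and state.time >= switch_iter[0][0] - 0.5 * params.dt:
            _, new_pH = switch_iter.pop(0)
            state = _set_pH(state, new_pH)
            positions = state.positions
            current_pH = new_pH
        pairs = nlist.pairs(positions, state.box)
        _advance_inplace(positions, state.charges, topo, state.box, params,
                         model, rng, pairs, d)
        state.time = frames[0].time + (k + 1) * params.dt
        if (k + 1) % frame_stride == 0:
            frames.append(state.copy())
    if params.n_steps % frame_stride != 0:
        frames.append(state.copy())

    meta = {
        "sim_params": asdict(params),
        "protocol": [list(e) for e in protocol.schedule],
        "final_pH": current_pH,
        "frame_stride": frame_stride,
        "n_frames": len(frames),
    }
    return Trajectory(frames=frames, metadata=meta)


def _set_pH(state: SystemState, pH: float) -> SystemState:
    """Reassign every rod's charges for the given pH (template shared)."""
    new_template = assign_charges(state.template, pH)
    q_rod = new_template.charge_array()
    new = state.copy()
    new.template = new_template
    if state.n_beads:
        for beads in state.rod_slices():
            if len(beads) == new_template.n_beads:
                new.charges[beads] = q_rod
    return new


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def _frame_to_xyz(f: SystemState) -> str:
    buf = io.StringIO()
    buf.write(f"{f.n_beads}\n")
    box = f.box
    buf.write(
        f'Lattice="{box.lx:.10g} 0 0 0 {box.ly:.10g} 0 0 0 {box.lz:.10g}" '
        f'Properties=species:S:1:pos:R:3:rod:I:1:charge:R:1 '
        f'Time={f.time:.10g}\n')
    for p, r, q in zip(f.positions, f.rod_index, f.charges):
        buf.write(f"C {p[0]:.10g} {p[1]:.10g} {p[2]:.10g} {int(r)} {q:.10g}\n")
    return buf.getvalue()


def write_xyz(traj: Trajectory, path) -> None:
    """Extended-XYZ trajectory: one block per frame, per-bead rod id and
    charge as extra columns."""
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write(_frame_to_xyz(f))


def read_xyz(path, template: ChargedRod) -> Trajectory:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        n = int(lines[k])
        header = lines[k + 1]
        lat = header.split('"')[1].split()
        box = Box(float(lat[0]), float(lat[4]), float(lat[8]))
        t = float(header.rsplit("Time=", 1)[1].split()[0])
        pos = np.empty((n, 3))
        rod = np.empty(n, dtype=np.intp)
        q = np.empty(n)
        for i in range(n):
            parts = lines[k + 2 + i].split()
            pos[i] = [float(x) for x in parts[1:4]]
            rod[i] = int(parts[4])
            q[i] = float(parts[5])
        frames.append(SystemState(pos, rod, q, box, template, time=t))
        k += 2 + n
    return Trajectory(frames=frames, metadata={})


def write_hdf5(traj: Trajectory, path) -> None:
    """HDF5 layout: /positions (F,N,3), /charges (F,N), /rod_index (N,),
    /time (F,), box lengths and JSON metadata as root attributes."""
    import h5py

    F = len(traj.frames)
    n = traj.frames[0].n_beads if F else 0
    with h5py.File(path, "w") as h5:
        h5.create_dataset("positions",
                          data=np.array([f.positions for f in traj.frames]))
        h5.create_dataset("charges",
                          data=np.array([f.charges for f in traj.frames]))
        h5.create_dataset("rod_index",
                          data=traj.frames[0].rod_index if F else np.zeros(0, np.intp))
        h5.create_dataset("time", data=np.array([f.time for f in traj.frames]))
        if F:
            b = traj.frames[0].box
            h5.attrs["box"] = [b.lx, b.ly, b.lz]
        h5.attrs["metadata"] = json.dumps(traj.metadata, sort_keys=True)
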