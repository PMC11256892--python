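"""colribbon: pH-driven disassembly and reassembly of collagen nanoribbons.

A coarse-grained model of collagen-mimetic charged rods on a charged
substrate, with Brownian dynamics under a pH protocol, D-band structure
analysis (backbone mass profiles, periodograms), a synthetic HS-AFM
topograph emulator, and tapping-mode cantilever force estimation.
"""

from .model import (ChargeSite, ChargedRod, ElectrostaticParams, LJParams,
                    SurfaceParams, BufferSpec, assign_charges, debye_length,
                    bjerrum_length, ionic_strength, pair_energy_dh,
                    pair_energy_lj, surface_energy, collagen_mimetic_rod,
                    default_electrostatics, default_lj, default_surface)
from .forces import Box, Topology, compute_energy_forces
from .dynamics import (SystemState, SimParams, PHProtocol, Trajectory,
                       ModelParams, build_ribbon_state, free_gas_state, step,
                       run_protocol, write_xyz, read_xyz, write_hdf5)
from .metrics import (ClusterSet, BackboneCurve, MassProfile, Periodogram,
                      find_clusters, largest_cluster_fraction,
                      backbone_spline, principal_axis_curve, mass_profile,
                      periodogram, dominant_period, profile_similarity,
                      similarity_null)
from .afm import (Topograph, TipModel, NoiseModel, RibbonGeometrySpec,
                  render_topograph, cross_section, height_timetrace,
                  emulate_disassembly)
from .tapping import (CantileverParams, ContactModel, ForceEstimate,
                      free_amplitude_response, simulate_tapping,
                      setpoint_to_force)
from .pipeline import (ExchangeSpec, RunConfig, exchange_time,
                       run_full_cycle, default_demo_config)

__version__ = "0.1.0"


def total_energy(state, es, lj, surf, pairs=None):
    """Total system energy in kT (nonbonded + bonded + surface terms)."""
    breakdown, _ = compute_energy_forces(
        state.positions, state.charges, state.topology(), state.box,
        es, lj, surf, pairs=pairs)
    return breakdown.total
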