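"""Ribbon construction, the Brownian integrator and trajectory handling."""

import numpy as np
import pytest

import colribbon as cb
from colribbon.dynamics import (PHProtocol, SimParams, TimestepError, step,
                                run_protocol, read_xyz, write_xyz, write_hdf5)
from colribbon.forces import Box, NeighborList


def min_pair_distance(state):
    """Brute-force all-pairs minimum distance (periodic in x, y)."""
    p = state.positions
    ii, jj = np.triu_indices(len(p), k=1)
    d = p[jj] - p[ii]
    d[:, 0] -= state.box.lx * np.round(d[:, 0] / state.box.lx)
    d[:, 1] -= state.box.ly * np.round(d[:, 1] / state.box.ly)
    return np.linalg.norm(d, axis=1).min()


class TestRibbonBuilder:
    def test_five_molecule_fibril_geometry(self, small_rod):
        st = cb.build_ribbon_state(1, 5, 3.0, small_rod)
        assert st.n_rods == 5
        starts = [st.positions[beads][0, 0] for beads in st.rod_slices()]
        offsets = np.diff(sorted(starts))
        assert np.allclose(offsets, 3.0)

    def test_empty_state(self, small_rod):
        st = cb.build_ribbon_state(0, 5, 3.0, small_rod)
        assert st.n_beads == 0 and st.n_rods == 0

    def test_no_bead_overlaps(self, small_rod):
        """Minimum inter-bead distance >= 0.9 x diameter (all-pairs scan)."""
        st = cb.build_ribbon_state(2, 7, 3.0, small_rod)
        assert min_pair_distance(st) >= 0.9 * small_rod.bead_diameter

    def test_overlapping_stagger_rejected(self, small_rod):
        # 5 rows, stagger so small that same-row molecules collide
        with pytest.raises(ValueError, match="cannot fit"):
            cb.build_ribbon_state(1, 8, 1.0, small_rod)

    def test_box_too_small_rejected(self, small_rod):
        with pytest.raises(ValueError, match="cannot fit"):
            cb.build_ribbon_state(1, 5, 3.0, small_rod,
                                  box=Box(10.0, 10.0, 5.0))


class TestStep:
    def test_zero_temperature_no_force_is_stationary(self, small_rod,
                                                     model_params):
        st = cb.build_ribbon_state(1, 1, 3.0, small_rod)
        st.charges[:] = 0.0
        params = SimParams(temperature=0.0, dt=1e-3)
        lj_off = cb.LJParams(sigma=1.5, epsilon=0.0, cutoff=3.75)
        model = cb.ModelParams(model_params.es, lj_off,
                               cb.SurfaceParams(mode="off"))
        new = step(st, params, model, np.random.default_rng(0))
        assert np.allclose(new.positions, st.positions, atol=1e-12)

    def test_zero_temperature_constant_force_drifts_exactly(self, model_params):
        """A single charged free bead in the substrate field moves (F/gamma)dt."""
        rod = cb.ChargedRod(n_beads=2)
        box = Box(20, 20, 10)
        st = cb.SystemState(np.array([[5.0, 5.0, 2.0]]), np.array([0]),
                            np.array([1.0]), box, rod)
        surf = cb.default_surface()
        model = cb.ModelParams(model_params.es,
                               cb.LJParams(1.5, 0.0, 3.75), surf)
        params = SimParams(temperature=0.0, dt=1e-3, friction=2.0)
        fz = -surf.strength * 1.0 * np.exp(-2.0 / surf.decay_length) \
            / surf.decay_length
        new = step(st, params, model, np.random.default_rng(0))
        assert new.positions[0, 2] - 2.0 == pytest.approx(fz * 1e-3 / 2.0,
                                                          rel=1e-12)

    def test_timestep_guard_aborts(self, model_params):
        """Unclamped huge displacement raises the too-large-step error."""
        rod = cb.ChargedRod(n_beads=2)
        box = Box(20, 20, 10)
        pos = np.array([[5.0, 5.0, 2.0], [5.0 + 1.01, 5.0, 2.0]])
        st = cb.SystemState(pos, np.array([0, 1]), np.zeros(2), box, rod)
        model = cb.ModelParams(model_params.es,
                               cb.LJParams(1.5, 1.0, 3.75),
                               cb.SurfaceParams(mode="off"))
        params = SimParams(temperature=0.0, dt=1.0, max_move=None)
        with pytest.raises(TimestepError, match="timestep too large"):
            step(st, params, model, np.random.default_rng(0))

    def test_free_diffusion_einstein_relation(self):
        """Per-axis MSD of 10^3 free beads over 10^4 steps equals 2(kT/gamma)t
        within 3 standard errors."""
        n, n_steps, dt = 1000, 10_000, 5e-3
        box = Box(1000.0, 1000.0, 1000.0)
        rod = cb.ChargedRod(n_beads=2)
        st = cb.free_gas_state(n, box, rod, seed=7, z_band=(400.0, 600.0))
        start = st.positions.copy()
        model = cb.ModelParams(cb.default_electrostatics(),
                               cb.LJParams(1.5, 0.0, 3.75),
                               cb.SurfaceParams(mode="off"))
        params = SimParams(dt=dt, max_move=None)
        rng = np.random.default_rng(11)
        nlist = NeighborList(6.0)
        topo = st.topology()
        for _ in range(n_steps):
            st = step(st, params, model, rng, nlist=nlist, topology=topo)
        t = n_steps * dt
        expected = 2.0 * 1.0 * t        # kT/gamma = 1 nm^2 per unit time
        disp = st.positions - start
        disp[:, 0] -= box.lx * np.round(disp[:, 0] / box.lx)
        disp[:, 1] -= box.ly * np.round(disp[:, 1] / box.ly)
        disp2 = disp ** 2
        for axis in range(3):
            msd = disp2[:, axis].mean()
            se = disp2[:, axis].std(ddof=1) / np.sqrt(n)
            assert abs(msd - expected) < 3.0 * se


class TestProtocolRuns:
    @pytest.fixture
    def tiny_run(self, small_rod, model_params):
        st = cb.build_ribbon_state(1, 3, 3.0, small_rod)
        protocol = PHProtocol(((0.0, 7.4), (1.0, 2.2)))
        params = SimParams(dt=2e-3, n_steps=1000, seed=42)
        return st, protocol, params, model_params

    def test_determinism_byte_identical_files(self, tiny_run, tmp_path):
        st, protocol, params, model = tiny_run
        paths = []
        for k in range(2):
            traj = run_protocol(st, protocol, params, model, frame_stride=200)
            p = tmp_path / f"run{k}.xyz"
            write_xyz(traj, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_charges_switch_at_protocol_time(self, tiny_run):
        st, protocol, params, model = tiny_run
        traj = run_protocol(st, protocol, params, model, frame_stride=200)
        q_first = traj.frames[0].charges
        q_last = traj.frames[-1].charges
        assert (q_first < 0).any()
        assert not (q_last < 0).any()          # acidic: negatives removed
        assert (q_last > 0).sum() > (q_first > 0).sum()

    def test_single_entry_protocol_keeps_charges(self, tiny_run):
        st, _, params, model = tiny_run
        traj = run_protocol(st, PHProtocol(((0.0, 7.4),)), params, model,
                            frame_stride=500)
        for f in traj.frames:
            assert np.array_equal(f.charges, traj.frames[0].charges)

    def test_zero_noise_quench_descends_energy(self, small_rod, model_params):
        """T = 0 integration is clamped gradient descent: total energy is
        non-increasing between frames."""
        st = cb.build_ribbon_state(1, 3, 3.0, small_rod)
        rng = np.random.default_rng(5)
        st.positions += rng.normal(0, 0.1, st.positions.shape)
        st.positions[:, 2] = np.clip(st.positions[:, 2], 0.8, None)
        params = SimParams(temperature=0.0, dt=5e-4, n_steps=400, seed=1)
        traj = run_protocol(st, PHProtocol(((0.0, 7.4),)), params,
                            model_params, frame_stride=40)
        energies = [cb.total_energy(f, model_params.es, model_params.lj,
                                    model_params.surf)
                    for f in traj.frames]
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-9)

    def test_uniform_translation_preserves_distances(self, small_rod):
        """Periodic wrap is an isometry for whole-system translations."""
        st = cb.build_ribbon_state(1, 5, 3.0, small_rod)
        d0 = min_pair_distance(st)
        shifted = st.copy()
        shifted.positions[:, 0] = (shifted.positions[:, 0] + 17.3) % st.box.lx
        shifted.positions[:, 1] = (shifted.positions[:, 1] + 29.9) % st.box.ly
        assert min_pair_distance(shifted) == pytest.approx(d0, rel=1e-12)

    def test_xyz_roundtrip_and_hdf5(self, tiny_run, tmp_path):
        st, protocol, params, model = tiny_run
        traj = run_protocol(st, protocol, params, model, frame_stride=500)
        p = tmp_path / "t.xyz"
        write_xyz(traj, p)
        back = read_xyz(p, st.template)
        assert len(back) == len(traj)
        last = traj.frames[-1]
        assert np.allclose(back.frames[-1].positions, last.positions,
                           atol=1e-9)
        assert np.array_equal(back.frames[-1].charges, last.charges)
        h5path = tmp_path / "t.h5"
        write_hdf5(traj, h5path)
        import h5py
        with h5py.File(h5path) as h5:
            assert h5["positions"].shape == (len(traj), st.n_beads, 3)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            PHProtocol(((1.0, 7.4),))
        with pytest.raises(ValueError):
            PHProtocol(((0.0, 7.4), (0.0, 2.2)))
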