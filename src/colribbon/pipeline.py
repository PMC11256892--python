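"""End-to-end orchestration: build ribbon -> pH-cycle simulation ->
profile/period/similarity analysis -> synthetic AFM rendering -> JSON report.

Every stage is a thin call into the library modules; the pipeline adds
configuration handling, a config hash embedded in all outputs, and a
machine-readable report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import afm, metrics
from .dynamics import (Box, ModelParams, PHProtocol, SimParams, SystemState,
                       Trajectory, build_ribbon_state, run_protocol,
                       write_xyz)
from .model import (BufferSpec, collagen_mimetic_rod, debye_length,
                    default_electrostatics, default_lj, default_surface)

__all__ = ["ExchangeSpec", "RunConfig", "exchange_time", "run_full_cycle",
           "default_demo_config", "verify_report"]

SCHEMA_VERSION = 1
log = logging.getLogger("colribbon.pipeline")


@dataclass(frozen=True)
class ExchangeSpec:
    """Fluid-cell exchange: volume under the tip (uL) and pump flow (uL/s)."""

    cell_volume: float = 2.0
    flow_rate: float = 2.0

    def __post_init__(self) -> None:
        if self.cell_volume < 0 or self.flow_rate <= 0:
            raise ValueError("cell_volume must be >= 0 and flow_rate > 0")


def exchange_time(spec: ExchangeSpec) -> float:
    """Time (s) to replace the solution under the tip: volume / flow rate.

    With the experimental 2 uL cell and 2 uL/s flow this bounds the pH
    equilibration time at 1 s, fast compared with the 1 frame/s imaging."""
    return spec.cell_volume / spec.flow_rate


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Complete, serialisable description of one pH-cycle run."""

    # system
    n_fibrils: int = 1
    molecules_per_fibril: int = 6
    n_beads: int = 10
    bead_spacing: float = 1.5
    bead_diameter: float = 1.5
    stagger: float = 3.0
    box: tuple[float, float, float] = (30.0, 30.0, 5.0)
    #: charge motif tiled along the rod: list of (site_class, pKa) with
    #: site_class in {acidic, basic, neutral}; None -> the default motif
    charge_motif: tuple[tuple[str, float | None], ...] | None = None
    #: electrolyte composition [(name, molar, charge), ...]; when given, the
    #: Debye length is computed from it instead of taken from debye_length
    buffer_species: tuple[tuple[str, float, int], ...] | None = None
    # interactions
    debye_length: float = 1.5
    bjerrum_length: float = 7.0
    es_cutoff: float = 6.0
    lj_epsilon: float = 0.15
    lj_cutoff: float = 3.75
    surface_strength: float = 2.0
    surface_decay: float = 1.0
    surface_mode: str = "on"
    # protocol (reduced time units)
    protocol: tuple[tuple[float, float], ...] = ((0.0, 7.4), (60.0, 2.2),
                                                 (100.0, 7.4))
    # integration
    dt: float = 2e-3
    n_steps: int = 200_000
    frame_stride: int = 5000
    temperature: float = 300.0
    seed: int = 0
    # analysis
    contact_cutoff: float | None = None
    bin_width: float = 1.5
    period_band: tuple[float, float] = (2.5, 30.0)
    n_permutations: int = 500
    # rendering
    pixel_size: float = 1.0
    tip_radius: float = 2.0
    noise_rms: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("box", "period_band"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("protocol", "charge_motif", "buffer_species"):
            if d.get(key) is not None:
                d[key] = tuple(tuple(e) for e in d[key])
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def model_params(self) -> ModelParams:
        lam = self.debye_length
        if self.buffer_species is not None:
            lam = debye_length(BufferSpec(species=tuple(
                (n, c, z) for n, c, z in self.buffer_species),
                temperature=self.temperature))
        cutoff = max(self.es_cutoff, 3.0 * lam)
        return ModelParams(
            es=default_electrostatics(lam, self.bjerrum_length, cutoff),
            lj=default_lj(self.bead_diameter, self.lj_epsilon, self.lj_cutoff),
            surf=default_surface(self.surface_strength, self.surface_decay,
                                 self.surface_mode),
        )

    def template(self):
        kwargs = {}
        if self.charge_motif is not None:
            kwargs["motif"] = tuple(
                (cls, pka) for cls, pka in self.charge_motif)
        return collagen_mimetic_rod(n_beads=self.n_beads,
                                    bead_spacing=self.bead_spacing,
                                    bead_diameter=self.bead_diameter,
                                    **kwargs)

    def initial_state(self) -> SystemState:
        return build_ribbon_state(self.n_fibrils, self.molecules_per_fibril,
                                  self.stagger, self.template(),
                                  box=Box(*self.box))


def default_demo_config(seed: int = 0) -> RunConfig:
    """Small-system demo sized to run a full pH cycle in minutes on one CPU."""
    return RunConfig(seed=seed)


# ---------------------------------------------------------------------------
# Full cycle
# ---------------------------------------------------------------------------

def _largest_cluster_profile(state: SystemState, bin_width: float,
                             contact_cutoff=None) -> metrics.MassProfile:
    """Mass profile of the largest cluster along its backbone; falls back to
    the straight principal axis when the cluster is not elongated."""
    cs = metrics.find_clusters(state, contact_cutoff)
    cid = int(np.argmax(cs.masses))
    beads = metrics.cluster_beads(state, cs, cid)
    beads = _unwrap_cluster(beads, state.box)
    try:
        curve = metrics.backbone_spline(beads)
    except metrics.NotElongatedError:
        curve = metrics.principal_axis_curve(beads)
    return metrics.mass_profile(beads, curve, bin_width)


def _unwrap_cluster(beads: np.ndarray, box) -> np.ndarray:
    """Undo periodic x/y wrapping within one cluster (shift by the circular
    mean so the cluster is contiguous)."""
    out = beads.copy()
    for dim, L in ((0, box.lx), (1, box.ly)):
        ang = out[:, dim] * (2 * np.pi / L)
        mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
        out[:, dim] = np.mod(ang - mean + np.pi, 2 * np.pi) - np.pi
        out[:, dim] *= L / (2 * np.pi)
    return out


def run_full_cycle(config: RunConfig, out_dir) -> dict:
    """Simulate the pH cycle, analyse initial vs final structure, render
    synthetic AFM twins, and write a JSON report.  Deterministic for a fixed
    config (the seed is part of the config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    report: dict = {"schema_version": SCHEMA_VERSION, "config_hash": cfg_hash,
                    "seed": config.seed, "stages": []}
    t_start = _time.time()
    fh = logging.FileHandler(out / "run.log")
    fh.setLevel(logging.INFO)
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    log.info("run_full_cycle seed=%d config=%s", config.seed, cfg_hash)

    def stage(name):
        # timings go to the log only: the report must be seed-deterministic
        log.info("stage %s (t=%.1fs, config %s)", name,
                 _time.time() - t_start, cfg_hash)
        report["stages"].append(name)

    try:
        stage("build")
        state0 = config.initial_state()
        model = config.model_params()

        stage("simulate")
        if config.n_steps > 0:
            protocol = PHProtocol(config.protocol)
            params = SimParams(temperature=config.temperature, dt=config.dt,
                               n_steps=config.n_steps, seed=config.seed)
            traj = run_protocol(state0, protocol, params,
                                model, frame_stride=config.frame_stride)
        else:
            traj = Trajectory(frames=[state0], metadata={"n_frames": 1})
        traj.metadata["config_hash"] = cfg_hash
        write_xyz(traj, out / "trajectory.xyz")

        stage("analyze")
        fractions = [metrics.largest_cluster_fraction(f, config.contact_cutoff)
                     for f in traj.frames]
        times = [f.time for f in traj.frames]
        p_init = _largest_cluster_profile(traj.frames[0], config.bin_width,
                                          config.contact_cutoff)
        report["initial"] = _profile_block(p_init, config)
        metrics.profile_to_csv(p_init, out / "profile_initial.csv")
        report["largest_cluster_fraction"] = {
            "time": times, "value": [float(x) for x in fractions]}
        if len(traj.frames) > 1:
            p_final = _largest_cluster_profile(traj.frames[-1],
                                               config.bin_width,
                                               config.contact_cutoff)
            report["final"] = _profile_block(p_final, config)
            metrics.profile_to_csv(p_final, out / "profile_final.csv")
            rng = np.random.default_rng(config.seed + 1)
            obs, _null, pval = metrics.similarity_null(
                p_init, p_final, n_perm=config.n_permutations, rng=rng)
            report["similarity"] = {"score": obs, "p_value": pval,
                                    "n_permutations": config.n_permutations}

        stage("render")
        tip = afm.TipModel(radius=config.tip_radius)
        noise = afm.NoiseModel(rms=config.noise_rms, seed=config.seed)
        topo0 = afm.render_beads(traj.frames[0].positions,
                                 0.5 * config.bead_diameter, tip,
                                 config.pixel_size,
                                 extent=(config.box[0], config.box[1]),
                                 noise=noise)
        frames = [topo0]
        if len(traj.frames) > 1:
            frames.append(afm.render_beads(
                traj.frames[-1].positions, 0.5 * config.bead_diameter, tip,
                config.pixel_size, extent=(config.box[0], config.box[1]),
                noise=noise, frame_index=1,
                timestamp=traj.frames[-1].time))
        afm.write_tiff_stack(frames, out / "topographs.tif")

        report["files"] = {
            "trajectory": "trajectory.xyz",
            "topographs": "topographs.tif",
            "profile_initial": "profile_initial.csv",
        }
        if len(traj.frames) > 1:
            report["files"]["profile_final"] = "profile_final.csv"
    except Exception as exc:  # annotate with the failing stage
        last = report["stages"][-1] if report["stages"] else "init"
        log.error("stage %r failed: %s", last, exc)
        log.removeHandler(fh)
        fh.close()
        raise RuntimeError(f"pipeline stage {last!r} failed: {exc}") from exc
    log.info("done (%.1f s)", _time.time() - t_start)
    log.removeHandler(fh)
    fh.close()

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "config.json").write_text(
        json.dumps({"config_hash": cfg_hash, **config.to_dict()},
                   indent=2, sort_keys=True))
    return report


def _profile_block(profile: metrics.MassProfile, config: RunConfig) -> dict:
    block = {"n_bins": int(len(profile.mass)),
             "total_mass": float(profile.mass.sum())}
    try:
        pg = metrics.periodogram(profile)
        block["dominant_period_nm"] = metrics.dominant_period(
            pg, config.period_band)
    except ValueError:
        block["dominant_period_nm"] = None
    return block


def verify_report(out_dir) -> bool:
    """Re-check that the config hash embedded in the report matches the
    stored configuration."""
    out = Path(out_dir)
    report = json.loads((out / "report.json").read_text())
    stored = json.loads((out / "config.json").read_text())
    h = stored.pop("config_hash")
    recomputed = RunConfig.from_dict(stored).hash()
    return report["config_hash"] == h == recomputed
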