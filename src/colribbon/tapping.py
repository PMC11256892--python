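"""Amplitude-modulation (tapping-mode) AFM cantilever dynamics.

The cantilever is reduced to its fundamental eigenmode: a driven, damped
point-mass oscillator

    m u'' + (m w0 / Q) u' + k u = F0 cos(w t) + F_ts(z_c + u),

with m = k / w0^2, driven at resonance with F0 chosen so the free oscillation
amplitude equals A0.  The tip-sample force F_ts is the DMT model (constant
van der Waals adhesion outside contact, Hertz repulsion plus the adhesion
minimum inside), the standard default of dynamic-AFM simulators.  Because the
peak repulsive force cannot be measured directly while imaging, it is
estimated here by integrating the oscillator at the operating amplitude
setpoint A_sp.

Units: nm, kHz (time integrated in microseconds), force constants in nN/nm;
forces are reported in pN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]

__all__ = ["CantileverParams", "ContactModel", "ForceEstimate",
           "free_amplitude_response", "simulate_tapping", "setpoint_to_force",
           "SetpointUnreachableError"]


@dataclass(frozen=True)
class CantileverParams:
    """First-eigenmode cantilever description.

    resonant_frequency f in kHz, force_constant k in nN/nm, quality factor Q,
    free amplitude A0 and amplitude setpoint Asp in nm.
    """

    resonant_frequency: float
    force_constant: float
    quality_factor: float
    free_amplitude: float
    setpoint_amplitude: float

    def __post_init__(self) -> None:
        vals = (self.resonant_frequency, self.force_constant,
                self.quality_factor, self.free_amplitude,
                self.setpoint_amplitude)
        if any(v <= 0 for v in vals):
            raise ValueError("all cantilever parameters must be positive")
        if self.setpoint_amplitude > self.free_amplitude:
            raise ValueError("Asp must not exceed A0")

    @property
    def omega0(self) -> float:
        """Angular resonance frequency in rad/us."""
        return 2.0 * math.pi * self.resonant_frequency * 1e-3

    @property
    def mass(self) -> float:
        """Effective modal mass in nN us^2 / nm."""
        return self.force_constant / self.omega0 ** 2


@dataclass(frozen=True)
class ContactModel:
    """DMT tip-sample force: Hamaker constant in zJ, tip radius in nm,
    sample Young's modulus in MPa, intermolecular distance a0 in nm.  The
    tip is treated as rigid; the effective modulus is E/(1 - nu^2)."""

    model: str = "DMT"
    hamaker: float = 3.0
    tip_radius: float = 2.0
    sample_modulus: float = 300.0
    poisson: float = 0.3
    intermolecular_distance: float = 0.165

    def __post_init__(self) -> None:
        if self.model != "DMT":
            raise ValueError("only the DMT contact model is implemented")
        if min(self.hamaker, self.tip_radius, self.sample_modulus,
               self.intermolecular_distance) <= 0:
            raise ValueError("contact parameters must be positive")

    @property
    def effective_modulus(self) -> float:
        return self.sample_modulus / (1.0 - self.poisson ** 2)


@dataclass
class ForceEstimate:
    peak_force: float            # pN, maximum repulsive F_ts per cycle (>= 0)
    mean_deflection: float       # nm
    contact_time_fraction: float
    amplitude: float             # nm, steady-state oscillation amplitude
    mean_distance: float         # nm, cantilever rest position above sample
    converged: bool = True


class SetpointUnreachableError(ValueError):
    pass


def free_amplitude_response(c: CantileverParams, drive_frequency: float,
                            drive_force: float) -> float:
    """Closed-form steady-state amplitude (nm) of the free driven oscillator.

    At resonance this reduces to Q * F / k; in the static limit to F / k.
    """
    w = 2.0 * math.pi * drive_frequency * 1e-3
    w0 = c.omega0
    m = c.mass
    denom = math.sqrt((w0 ** 2 - w ** 2) ** 2 + (w0 * w / c.quality_factor) ** 2)
    return drive_force / (m * denom)


@njit(cache=True)
def _dmt_force(gap: float, hamaker: float, radius: float, emod: float,
               a0: float) -> float:
    """DMT force in nN (attractive negative, repulsive positive)."""
    if gap >= a0:
        return -hamaker * radius / (6.0 * gap * gap) * 1e-3
    adhesion = -hamaker * radius / (6.0 * a0 * a0) * 1e-3
    indent = a0 - gap
    hertz = (4.0 / 3.0) * emod * math.sqrt(radius) * indent * math.sqrt(indent) * 1e-3
    return adhesion + hertz


@njit(cache=True)
def _integrate(zc: float, w0: float, w: float, Q: float, k: float, m: float,
               F0: float, hamaker: float, radius: float, emod: float, a0: float,
               n_settle: int, n_measure: int, steps_per_cycle: int,
               use_contact: bool):
    """RK4 integration; returns (amplitude, mean deflection, peak repulsive
    force nN, contact fraction, per-quarter amplitudes of the window)."""
    dt = (2.0 * math.pi / w) / steps_per_cycle
    u = 0.0
    v = 0.0
    t = 0.0
    gamma = m * w0 / Q

    def acc(tt, uu, vv):
        f = F0 * math.cos(w * tt) - gamma * vv - k * uu
        if use_contact:
            f += _dmt_force(zc + uu, hamaker, radius, emod, a0)
        return f / m

    n_total = (n_settle + n_measure) * steps_per_cycle
    meas_start = n_settle * steps_per_cycle
    umax = -1e30
    umin = 1e30
    usum = 0.0
    fpeak = 0.0
    ncontact = 0
    nmeas = 0
    q_amp = np.zeros(4)
    q_len = (n_measure * steps_per_cycle) // 4
    q_max = np.full(4, -1e30)
    q_min = np.full(4, 1e30)
    for i in range(n_total):
        k1v = acc(t, u, v)
        k1u = v
        k2v = acc(t + 0.5 * dt, u + 0.5 * dt * k1u, v + 0.5 * dt * k1v)
        k2u = v + 0.5 * dt * k1v
        k3v = acc(t + 0.5 * dt, u + 0.5 * dt * k2u, v + 0.5 * dt * k2v)
        k3u = v + 0.5 * dt * k2v
        k4v = acc(t + dt, u + dt * k3u, v + dt * k3v)
        k4u = v + dt * k3v
        u += dt * (k1u + 2 * k2u + 2 * k3u + k4u) / 6.0
        v += dt * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0
        t += dt
        if i >= meas_start:
            j = i - meas_start
            usum += u
            nmeas += 1
            if u > umax:
                umax = u
            if u < umin:
                umin = u
            qi = min(j // max(q_len, 1), 3)
            if u > q_max[qi]:
                q_max[qi] = u
            if u < q_min[qi]:
                q_min[qi] = u
            if use_contact:
                gap = zc + u
                f_ts = _dmt_force(gap, hamaker, radius, emod, a0)
                if f_ts > fpeak:
                    fpeak = f_ts
                if gap < a0:
                    ncontact += 1
    for qi in range(4):
        q_amp[qi] = 0.5 * (q_max[qi] - q_min[qi])
    amp = 0.5 * (umax - umin)
    return amp, usum / nmeas, fpeak, ncontact / nmeas, q_amp


def simulate_tapping(c: CantileverParams, contact: ContactModel,
                     mean_tip_sample_distance: float,
                     n_measure_cycles: int = 200,
                     n_settle_cycles: int = 60,
                     steps_per_cycle: int = 1500,
                     use_contact: bool = True) -> ForceEstimate:
    """Integrate the tapping oscillator at a fixed cantilever rest height.

    The drive is at resonance with amplitude F0 = k A0 / Q, so far from the
    surface the oscillation amplitude equals A0.  Reports the steady-state
    amplitude, the peak repulsive tip-sample force per cycle, the mean
    deflection and the fraction of time in mechanical contact.  If the
    amplitude has not converged to a steady value (beats), the estimate is
    flagged via ``converged=False`` and a warning.
    """
    F0 = c.force_constant * c.free_amplitude / c.quality_factor
    amp, mean_u, fpeak_nN, cfrac, q_amp = _integrate(
        mean_tip_sample_distance, c.omega0, c.omega0, c.quality_factor,
        c.force_constant, c.mass, F0, contact.hamaker, contact.tip_radius,
        contact.effective_modulus, contact.intermolecular_distance,
        n_settle_cycles, n_measure_cycles, steps_per_cycle, use_contact)
    converged = bool(np.ptp(q_amp) < max(0.02, 0.01 * c.free_amplitude))
    if not converged:
        warnings.warn(
            f"oscillation amplitude not steady (quarter-window amplitudes "
            f"{np.round(q_amp, 3)}); estimate flagged", RuntimeWarning)
    return ForceEstimate(peak_force=max(fpeak_nN, 0.0) * 1e3,
                         mean_deflection=float(mean_u),
                         contact_time_fraction=float(cfrac),
                         amplitude=float(amp),
                         mean_distance=mean_tip_sample_distance,
                         converged=converged)


def setpoint_to_force(c: CantileverParams, contact: ContactModel,
                      Asp: float | None = None, tolerance: float = 0.01,
                      **sim_kwargs) -> ForceEstimate:
    """Peak-force estimate at an amplitude setpoint.

    Bisects the cantilever rest height until the simulated amplitude matches
    ``Asp`` (default: the cantilever's setpoint_amplitude) within
    ``tolerance`` nm, on the repulsive (high-amplitude) branch.  Asp == A0
    returns the free state with zero force.
    """
    if Asp is None:
        Asp = c.setpoint_amplitude
    if Asp > c.free_amplitude:
        raise ValueError("Asp must not exceed A0")
    if Asp == c.free_amplitude:
        return ForceEstimate(peak_force=0.0, mean_deflection=0.0,
                             contact_time_fraction=0.0,
                             amplitude=c.free_amplitude,
                             mean_distance=math.inf)
    # The amplitude-distance curve is only monotone on the repulsive branch
    # approached from afar; walk down from the free regime until the
    # amplitude first crosses the setpoint, then bisect that local bracket.
    hi = c.free_amplitude + 5.0 * contact.intermolecular_distance + 1.0
    est_hi = simulate_tapping(c, contact, hi, **sim_kwargs)
    step_nm = 0.1 * c.free_amplitude
    lo = hi
    est_lo = est_hi
    lo_min = -2.0 * c.free_amplitude
    while est_lo.amplitude > Asp:
        hi, est_hi = lo, est_lo
        lo -= step_nm
        if lo < lo_min:
            raise SetpointUnreachableError(
                f"setpoint {Asp} nm below the reachable amplitude range "
                f"[{est_lo.amplitude:.3f}, {est_hi.amplitude:.3f}] nm on "
                "the repulsive branch")
        est_lo = simulate_tapping(c, contact, lo, **sim_kwargs)
    est = est_lo
    for _ in range(60):
        if abs(est.amplitude - Asp) < tolerance:
            return est
        mid = 0.5 * (lo + hi)
        est = simulate_tapping(c, contact, mid, **sim_kwargs)
        if est.amplitude > Asp:
            hi = mid
        else:
            lo = mid
    warnings.warn("setpoint bisection did not converge to tolerance",
                  RuntimeWarning)
    return est
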