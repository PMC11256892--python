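"""Quantitative structure analysis of rod assemblies.

Implements the analysis chain used on both simulated configurations and
synthetic AFM topographs: contact clustering of rods, backbone extraction by
a smoothing spline, mass (or height) profiles along the backbone arclength,
windowed periodograms of those profiles, dominant-period (D-band) estimation
and an alignment-invariant similarity score between profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .dynamics import SystemState
from .forces import candidate_pairs_tree

__all__ = ["ClusterSet", "BackboneCurve", "MassProfile", "Periodogram",
           "find_clusters", "largest_cluster_fraction", "backbone_spline",
           "principal_axis_curve", "mass_profile", "periodogram",
           "dominant_period", "profile_similarity", "similarity_null"]


@dataclass
class ClusterSet:
    """Partition of rods into contact clusters."""

    labels: np.ndarray     # cluster id per rod
    masses: np.ndarray     # bead count per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.masses)


@dataclass
class BackboneCurve:
    """Arclength-parametrised space curve through an elongated cluster."""

    control_points: np.ndarray   # (M, 3) nm, densely sampled along the curve
    arclength: float             # nm

    def arclengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.control_points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class MassProfile:
    """1-D mass (bead count) or height (nm) versus backbone arclength."""

    bin_centers: np.ndarray
    mass: np.ndarray
    bin_width: float
    source: str = "beads"        # "beads" (counts) or "topograph" (nm)


@dataclass
class Periodogram:
    spatial_frequencies: np.ndarray    # 1/nm, uniformly spaced from 0
    power: np.ndarray


class NotElongatedError(ValueError):
    """Cluster too isotropic for a backbone spline; use
    :func:`principal_axis_curve` for a straight-axis profile instead."""


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def find_clusters(state: SystemState, contact_cutoff: float | None = None
                  ) -> ClusterSet:
    """Single-linkage clustering of rods: two rods are linked iff any pair of
    their beads lies within ``contact_cutoff`` (default 1.5 x bead diameter).
    """
    if contact_cutoff is None:
        contact_cutoff = 1.5 * state.template.bead_diameter
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be > 0")
    rods = np.unique(state.rod_index)
    n_rods = len(rods)
    if n_rods == 0:
        return ClusterSet(labels=np.zeros(0, dtype=int), masses=np.zeros(0, dtype=int))
    rod_of = {r: k for k, r in enumerate(rods)}
    pairs = candidate_pairs_tree(state.positions, state.box, contact_cutoff)
    if len(pairs):
        ri = state.rod_index[pairs[:, 0]]
        rj = state.rod_index[pairs[:, 1]]
        inter = ri != rj
        rows = [rod_of[r] for r in ri[inter]]
        cols = [rod_of[r] for r in rj[inter]]
    else:
        rows, cols = [], []
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_rods, n_rods))
    n_comp, labels = connected_components(adj, directed=False)
    masses = np.array([
        int(np.sum(np.isin(state.rod_index, rods[labels == c])))
        for c in range(n_comp)])
    return ClusterSet(labels=labels, masses=masses)


def largest_cluster_fraction(state: SystemState,
                             contact_cutoff: float | None = None) -> float:
    """Mass fraction of the largest contact cluster (1.0 = fully assembled)."""
    cs = find_clusters(state, contact_cutoff)
    if cs.n_clusters == 0:
        return 0.0
    return float(cs.masses.max() / cs.masses.sum())


def cluster_beads(state: SystemState, clusters: ClusterSet, cluster_id: int
                  ) -> np.ndarray:
    rods = np.unique(state.rod_index)[clusters.labels == cluster_id]
    return state.positions[np.isin(state.rod_index, rods)]


# ---------------------------------------------------------------------------
# Backbone extraction
# ---------------------------------------------------------------------------

def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = points.mean(axis=0)
    centered = points - center
    cov = centered.T @ centered / max(len(points) - 1, 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return center, w[order], v[:, order]


def backbone_spline(beads: np.ndarray, smoothing: float | None = None,
                    n_samples: int = 512,
                    anisotropy_min: float = 2.0) -> BackboneCurve:
    """Smoothing spline through a bead cloud, ordered by projection on the
    first principal axis.

    Raises :class:`NotElongatedError` when the cloud's principal-axis
    anisotropy (sqrt of leading/second eigenvalue) is below
    ``anisotropy_min``; such clusters have no meaningful backbone and should
    be profiled along a straight principal axis instead.
    """
    beads = np.asarray(beads, dtype=float)
    if len(beads) < 2:
        raise ValueError("need at least 2 beads")
    center, w, v = _principal_axes(beads)
    ratio = np.sqrt(w[0] / w[1]) if w[1] > 0 else np.inf
    if ratio < anisotropy_min:
        raise NotElongatedError(
            f"anisotropy {ratio:.2f} < {anisotropy_min}: profile along the "
            "principal axis instead (principal_axis_curve)")
    t = (beads - center) @ v[:, 0]
    order = np.argsort(t, kind="stable")
    t_sorted = t[order]
    pts = beads[order]
    # average beads with (near-)identical projections so the parametrisation
    # is strictly monotone
    t_unique, inv = np.unique(np.round(t_sorted, 9), return_inverse=True)
    mean_pts = np.zeros((len(t_unique), 3))
    counts = np.bincount(inv, minlength=len(t_unique)).astype(float)
    for k in range(3):
        mean_pts[:, k] = np.bincount(inv, weights=pts[:, k],
                                     minlength=len(t_unique)) / counts
    if len(t_unique) < 2:
        raise NotElongatedError("beads project to a single point")
    if smoothing is None:
        # generous default: tolerate bead-scale transverse scatter
        smoothing = len(t_unique) * max(w[1], 1e-6)
    k_spl = min(3, len(t_unique) - 1)
    samples = np.empty((n_samples, 3))
    ts = np.linspace(t_unique[0], t_unique[-1], n_samples)
    for dim in range(3):
        spl = interpolate.UnivariateSpline(t_unique, mean_pts[:, dim],
                                           k=k_spl, s=smoothing)
        samples[:, dim] = spl(ts)
    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    arclength = float(seg.sum())
    end_to_end = float(np.linalg.norm(samples[-1] - samples[0]))
    if arclength < end_to_end:           # numerical guard; spline can only add length
        arclength = end_to_end
    return BackboneCurve(control_points=samples, arclength=arclength)


def principal_axis_curve(beads: np.ndarray, n_samples: int = 256) -> BackboneCurve:
    """Straight backbone along the first principal axis (fallback for
    non-elongated clusters)."""
    beads = np.asarray(beads, dtype=float)
    center, _w, v = _principal_axes(beads)
    t = (beads - center) @ v[:, 0]
    ts = np.linspace(t.min(), t.max(), n_samples)
    pts = center + ts[:, None] * v[:, 0]
    return BackboneCurve(control_points=pts,
                         arclength=float(t.max() - t.min()))


# ---------------------------------------------------------------------------
# Profiles and spectra
# ---------------------------------------------------------------------------

def mass_profile(beads: np.ndarray, curve: BackboneCurve, bin_width: float,
                 ) -> MassProfile:
    """Bead count per arclength bin: each bead is assigned to the bin of the
    arclength of its nearest point on the curve.  Total mass is conserved
    exactly."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    beads = np.asarray(beads, dtype=float)
    s_curve = curve.arclengths()
    pts = curve.control_points
    tree = cKDTree(pts)
    _, idx = tree.query(beads)
    # refine: project onto the polyline segments adjacent to the nearest
    # vertex, so the arclength is exact (not quantised to vertices)
    s = s_curve[idx].copy()
    best_d2 = np.sum((beads - pts[idx]) ** 2, axis=1)
    for lo in (idx - 1, idx):
        hi = lo + 1
        valid = (lo >= 0) & (hi < len(pts))
        a = pts[np.clip(lo, 0, len(pts) - 1)]
        b = pts[np.clip(hi, 0, len(pts) - 1)]
        ab = b - a
        denom = np.sum(ab ** 2, axis=1)
        tproj = np.clip(np.sum((beads - a) * ab, axis=1)
                        / np.where(denom > 0, denom, 1.0), 0.0, 1.0)
        proj = a + tproj[:, None] * ab
        d2 = np.sum((beads - proj) ** 2, axis=1)
        better = valid & (d2 < best_d2)
        seg_len = np.sqrt(denom)
        s = np.where(better,
                     s_curve[np.clip(lo, 0, len(pts) - 1)] + tproj * seg_len,
                     s)
        best_d2 = np.where(better, d2, best_d2)
    n_bins = max(int(np.ceil(curve.arclength / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(np.clip(s, 0, edges[-1] - 1e-12), bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return MassProfile(bin_centers=centers, mass=counts.astype(float),
                       bin_width=bin_width, source="beads")


def profile_from_series(positions: np.ndarray, values: np.ndarray,
                        source: str = "topograph") -> MassProfile:
    """Wrap an already-sampled 1-D series (e.g. an AFM cross-section) as a
    MassProfile; positions must be uniformly spaced."""
    positions = np.asarray(positions, dtype=float)
    dx = np.diff(positions)
    if len(dx) and not np.allclose(dx, dx[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform sampling")
    w = float(dx[0]) if len(dx) else 1.0
    return MassProfile(bin_centers=positions, mass=np.asarray(values, float),
                       bin_width=w, source=source)


def periodogram(profile: MassProfile, window: str = "hann") -> Periodogram:
    """Mean-removed, Hann-windowed power spectrum of a profile.

    The windowed signal is rescaled to the energy of the unwindowed
    mean-removed profile, so Parseval holds exactly: the power summed over
    the (one-sided, symmetry-doubled) spectrum equals the mean-removed
    profile variance times the bin count.
    """
    x = np.asarray(profile.mass, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 bins")
    dx = np.diff(profile.bin_centers)
    if not np.allclose(dx, profile.bin_width, rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform bins")
    xd = x - x.mean()
    if window == "hann":
        w = np.hanning(n) if n > 1 else np.ones(n)
    elif window in (None, "none", "boxcar"):
        w = np.ones(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    xw = xd * w
    e_raw = float(np.sum(xd ** 2))
    e_win = float(np.sum(xw ** 2))
    if e_win > 0:
        xw = xw * np.sqrt(e_raw / e_win)
    X = np.fft.rfft(xw)
    power = np.abs(X) ** 2 / n
    # double interior bins so the one-sided sum carries the full energy
    power[1:] *= 2.0
    if n % 2 == 0 and len(power) > 1:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=profile.bin_width)
    return Periodogram(spatial_frequencies=freqs, power=power)


def dominant_period(pg: Periodogram, band: tuple[float, float]) -> float:
    """Dominant spatial period (nm) within a period band (min_nm, max_nm).

    Picks the power-maximising frequency bin inside the band and refines it
    by 3-point parabolic interpolation on the power.
    """
    pmin, pmax = min(band), max(band)
    if pmin <= 0:
        raise ValueError("period band must be positive")
    f = pg.spatial_frequencies
    mask = (f > 0) & (f >= 1.0 / pmax) & (f <= 1.0 / pmin)
    if not np.any(mask):
        raise ValueError("empty band: no resolved frequencies in range")
    idx_band = np.flatnonzero(mask)
    k = idx_band[np.argmax(pg.power[idx_band])]
    f_peak = f[k]
    if 0 < k < len(f) - 1:
        y0, y1, y2 = pg.power[k - 1], pg.power[k], pg.power[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # genuine local maximum
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            f_peak = f[k] + delta * (f[1] - f[0])
    return float(1.0 / f_peak)


def profile_similarity(p1: MassProfile, p2: MassProfile) -> float:
    """Maximum normalised circular cross-correlation over all lags of the
    mean-removed profiles; 1 for identical (or circularly shifted) shapes.

    Profiles of unequal length are zero-padded (after mean removal) to the
    common length.  All-constant profiles have no shape and raise ValueError.
    """
    if not np.isclose(p1.bin_width, p2.bin_width, rtol=1e-6):
        raise ValueError("profiles must share a bin width")
    a = np.asarray(p1.mass, float)
    b = np.asarray(p2.mass, float)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("all-constant profile: similarity undefined")
    n = max(len(a), len(b))
    A = np.fft.rfft(a, n)
    B = np.fft.rfft(b, n)
    xcorr = np.fft.irfft(A * np.conj(B), n)
    return float(np.max(xcorr) / (na * nb))


def similarity_null(p1: MassProfile, p2: MassProfile, n_perm: int = 1000,
                    rng: np.random.Generator | None = None
                    ) -> tuple[float, np.ndarray, float]:
    """Permutation null for the similarity score.

    Returns (observed score, null distribution from bin-shuffled copies of
    p2, one-sided p-value with the +1 correction).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    obs = profile_similarity(p1, p2)
    null = np.empty(n_perm)
    shuffled = MassProfile(p2.bin_centers, p2.mass.copy(), p2.bin_width, p2.source)
    for k in range(n_perm):
        shuffled.mass = rng.permutation(p2.mass)
        null[k] = profile_similarity(p1, shuffled)
    p = (1.0 + np.sum(null >= obs)) / (n_perm + 1.0)
    return obs, null, float(p)


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def profile_to_csv(profile: MassProfile, path) -> None:
    pd.DataFrame({"position_nm": profile.bin_centers,
                  "value": profile.mass}).to_csv(path, index=False)


def periodogram_to_csv(pg: Periodogram, path) -> None:
    pd.DataFrame({"freq_per_nm": pg.spatial_frequencies,
                  "value": pg.power}).to_csv(path, index=False)


def curve_to_csv(curve: BackboneCurve, path) -> None:
    pd.DataFrame(curve.control_points,
                 columns=["x_nm", "y_nm", "z_nm"]).to_csv(path, index=False)
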