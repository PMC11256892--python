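"""Synthetic HS-AFM topograph emulation and image measurements.

Bead configurations or parametric collagen geometries are rasterised into a
sample height field, broadened by the scanning tip (grayscale morphological
dilation with a spherical tip: the image at x is the highest position of the
tip apex for which the tip ball touches the sample), pixelated and corrupted
with noise.  The module also implements the measurements made on such images:
height cross-sections, height-time traces at a point, and a layer-removal
emulator for the acid-driven disassembly of a nanoribbon.

Geometric conventions: heights in nm above the substrate plane (0), the fast
scan axis is x, images are stored as ``heights[row, col] = heights[y, x]``.
The default layer pitch equals one molecule diameter: measured heights of
molecules and nanofibrils are integer multiples of the 1.5 nm molecule
diameter, which is consistent with vertically commensurate stacking rather
than close packing (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["Topograph", "TipModel", "NoiseModel", "RibbonGeometrySpec",
           "Sphere", "CylinderX", "DBandSlab", "render_topograph",
           "render_primitives", "fibril_cross_section_primitives",
           "dband_ribbon_primitives", "cross_section", "axis_profile",
           "height_timetrace", "emulate_disassembly", "write_tiff_stack"]


@dataclass
class Topograph:
    """One synthetic AFM frame: a 2-D height grid with a physical pixel size."""

    heights: np.ndarray     # (ny, nx) nm, substrate = 0
    pixel_size: float       # nm / pixel
    timestamp: float = 0.0  # s
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or min(self.heights.shape) < 2:
            raise ValueError("heights must be a grid of at least 2x2 pixels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def extent(self) -> tuple[float, float]:
        """(x extent, y extent) in nm."""
        ny, nx = self.heights.shape
        return nx * self.pixel_size, ny * self.pixel_size


@dataclass(frozen=True)
class TipModel:
    """Spherical scanning tip of the given apex radius (nm)."""

    radius: float = 2.0
    shape: str = "sphere"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("tip radius must be > 0")
        if self.shape != "sphere":
            raise ValueError("only a spherical tip is modelled")


@dataclass(frozen=True)
class NoiseModel:
    """Pixel noise (Gaussian, rms in nm) plus a deterministic per-scan-line
    height creep of ``line_drift`` nm per line."""

    rms: float = 0.1
    line_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rms < 0:
            raise ValueError("rms must be >= 0")


NO_NOISE = NoiseModel(rms=0.0, line_drift=0.0, seed=0)


@dataclass(frozen=True)
class RibbonGeometrySpec:
    """Parametric D-banded collagen ribbon.

    molecule_length L and stagger D follow the canonical axial packing
    (L ~ 4.48 D): five staggered molecules per repeat column produce overlap
    regions (5 molecules deep, length L - 4D) alternating with gap regions
    (4 deep, length 5D - L).  ``gap_height``/``overlap_height`` are the
    rendered plateau heights of the D-band mode; ``layers`` with the
    molecule-diameter pitch governs the layered mode used by the disassembly
    emulator.
    """

    molecule_length: float = 300.0
    molecule_diameter: float = 1.5
    stagger: float = 300.0 / 4.48
    molecules_per_fibril: int = 5
    n_fibrils: int = 4
    layers: int = 2
    gap_height: float = 3.5
    overlap_height: float = 4.5
    n_periods: int = 12

    def __post_init__(self) -> None:
        if not self.molecule_length > self.stagger > 0:
            raise ValueError("need molecule_length > stagger > 0")
        if self.layers < 1:
            raise ValueError("layers must be >= 1")

    @property
    def overlap_length(self) -> float:
        """Axial length of the overlap region, L - 4D (clipped into (0, D))."""
        frac = self.molecule_length - 4.0 * self.stagger
        return float(np.clip(frac, 0.05 * self.stagger, 0.95 * self.stagger))

    @property
    def ribbon_width(self) -> float:
        return self.n_fibrils * 5 * self.molecule_diameter


# ---------------------------------------------------------------------------
# Sample primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        d2 = (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2
        h = np.full_like(x, -np.inf)
        m = d2 <= self.radius ** 2
        h[m] = self.center[2] + np.sqrt(self.radius ** 2 - d2[m])
        return h


@dataclass(frozen=True)
class CylinderX:
    """Cylinder with axis parallel to x, spanning [x0, x1], flat ends."""

    x0: float
    x1: float
    yc: float
    zc: float
    radius: float

    def height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dy2 = (y - self.yc) ** 2
        h = np.full_like(x, -np.inf)
        m = (dy2 <= self.radius ** 2) & (x >= self.x0) & (x <= self.x1)
        h[m] = self.zc + np.sqrt(self.radius ** 2 - dy2[m])
        return h


@dataclass(frozen=True)
class DBandSlab:
    """Flat-topped ribbon slab whose height alternates between gap and
    overlap plateaus with axial period D."""

    x0: float
    length: float
    y0: float
    width: float
    period: float
    overlap_length: float
    gap_height: float
    overlap_height: float

    def height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        h = np.full_like(x, -np.inf)
        m = (x >= self.x0) & (x <= self.x0 + self.length) & \
            (y >= self.y0) & (y <= self.y0 + self.width)
        phase = np.mod(x - self.x0, self.period)
        h[m] = np.where(phase[m] < self.overlap_length,
                        self.overlap_height, self.gap_height)
        return h


def fibril_cross_section_primitives(spec: RibbonGeometrySpec | None = None,
                                    length: float = 120.0,
                                    x0: float = 10.0, yc: float = 0.0
                                    ) -> list[CylinderX]:
    """Five molecules in the two-layer staggered cross-section of a
    nanofibril: three cylinders on the substrate and two in a second layer
    offset laterally by half a diameter, at the default layer pitch of one
    molecule diameter (apex = 2 diameters)."""
    d = spec.molecule_diameter if spec else 1.5
    r = 0.5 * d
    bottom_y = [yc - d, yc, yc + d]
    top_y = [yc - 0.5 * d, yc + 0.5 * d]
    prims = [CylinderX(x0, x0 + length, y, r, r) for y in bottom_y]
    prims += [CylinderX(x0, x0 + length, y, r + d, r) for y in top_y]
    return prims


def dband_ribbon_primitives(spec: RibbonGeometrySpec, x0: float = 20.0,
                            y0: float = 10.0) -> list[DBandSlab]:
    length = spec.n_periods * spec.stagger
    return [DBandSlab(x0=x0, length=length, y0=y0, width=spec.ribbon_width,
                      period=spec.stagger, overlap_length=spec.overlap_length,
                      gap_height=spec.gap_height,
                      overlap_height=spec.overlap_height)]


def layered_ribbon_primitives(spec: RibbonGeometrySpec, x0: float = 10.0,
                              y0: float = 10.0, layers: int | None = None
                              ) -> list[CylinderX]:
    """Uniform stacked-layer ribbon: each layer is a row of parallel
    molecules (cylinders) at a vertical pitch of one molecule diameter."""
    d = spec.molecule_diameter
    r = 0.5 * d
    n_mol = spec.n_fibrils * 5
    length = spec.n_periods * spec.stagger
    L = layers if layers is not None else spec.layers
    prims = []
    for k in range(L):
        for m in range(n_mol):
            prims.append(CylinderX(x0, x0 + length, y0 + (m + 0.5) * d,
                                   r + k * d, r))
    return prims


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _sample_height_field(primitives, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    h = np.zeros_like(x)
    for p in primitives:
        h = np.maximum(h, p.height(x, y))
    return h


def _tip_structure(radius: float, step: float) -> np.ndarray:
    """Grayscale structuring element of a spherical tip: sqrt(R^2-d^2)-R on
    the disk d <= R, strongly negative outside."""
    n = int(np.ceil(radius / step))
    ax = np.arange(-n, n + 1) * step
    dx, dy = np.meshgrid(ax, ax, indexing="xy")
    d2 = dx ** 2 + dy ** 2
    s = np.full(d2.shape, -1e9)
    m = d2 <= radius ** 2
    s[m] = np.sqrt(radius ** 2 - d2[m]) - radius
    return s


def dilate_heights(heights: np.ndarray, tip: TipModel, step: float) -> np.ndarray:
    """Tip-broadened image of a height field sampled with spacing ``step``."""
    structure = _tip_structure(tip.radius, step)
    return ndimage.grey_dilation(heights, structure=structure, mode="nearest")


def render_primitives(primitives, tip: TipModel, pixel_size: float,
                      extent: tuple[float, float],
                      noise: NoiseModel = NO_NOISE,
                      oversample: int = 4,
                      timestamp: float = 0.0, frame_index: int = 0
                      ) -> Topograph:
    """Render geometric primitives into one topograph.

    The sample surface is rasterised on an ``oversample``-times finer grid,
    dilated by the tip ball there, then sampled at the pixel centres, so tip
    contacts between pixel centres are captured.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    x_ext, y_ext = extent
    nx = max(int(round(x_ext / pixel_size)), 2)
    ny = max(int(round(y_ext / pixel_size)), 2)
    step = pixel_size / oversample
    xs = (np.arange(nx * oversample) + 0.5) * step
    ys = (np.arange(ny * oversample) + 0.5) * step
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    h_fine = _sample_height_field(primitives, gx, gy)
    h_fine = dilate_heights(h_fine, tip, step)
    off = oversample // 2
    img = h_fine[off::oversample, off::oversample][:ny, :nx]
    img = _apply_noise(img, noise)
    return Topograph(heights=img, pixel_size=pixel_size,
                     timestamp=timestamp, frame_index=frame_index)


def render_beads(positions: np.ndarray, bead_radius: float, tip: TipModel,
                 pixel_size: float, extent: tuple[float, float] | None = None,
                 noise: NoiseModel = NO_NOISE, oversample: int = 2,
                 timestamp: float = 0.0, frame_index: int = 0) -> Topograph:
    """Render a bead configuration (e.g. one simulation frame) by treating
    every bead as a sphere."""
    positions = np.asarray(positions, dtype=float)
    if extent is None:
        pad = 4 * bead_radius + tip.radius
        extent = (positions[:, 0].max() + pad, positions[:, 1].max() + pad)
    prims = [Sphere(tuple(p), bead_radius) for p in positions]
    return render_primitives(prims, tip, pixel_size, extent, noise,
                             oversample, timestamp, frame_index)


def render_topograph(geometry, tip: TipModel, pixel_size: float,
                     noise: NoiseModel = NO_NOISE, **kwargs) -> Topograph:
    """Dispatching front-end: accepts a RibbonGeometrySpec (D-band mode), a
    list of primitives, or an (N, 3) bead-position array with a
    ``bead_radius`` keyword."""
    if isinstance(geometry, RibbonGeometrySpec):
        prims = dband_ribbon_primitives(geometry)
        length = geometry.n_periods * geometry.stagger
        extent = kwargs.pop("extent", (length + 40.0,
                                       geometry.ribbon_width + 20.0))
        return render_primitives(prims, tip, pixel_size, extent, noise, **kwargs)
    geometry_arr = np.asarray(geometry, dtype=object)
    if geometry_arr.dtype == object and len(geometry) and hasattr(geometry[0], "height"):
        extent = kwargs.pop("extent")
        return render_primitives(list(geometry), tip, pixel_size, extent,
                                 noise, **kwargs)
    bead_radius = kwargs.pop("bead_radius")
    return render_beads(np.asarray(geometry, float), bead_radius, tip,
                        pixel_size, noise=noise, **kwargs)


def _apply_noise(img: np.ndarray, noise: NoiseModel) -> np.ndarray:
    if noise.rms == 0 and noise.line_drift == 0:
        return np.clip(img, 0.0, None)
    rng = np.random.default_rng(noise.seed)
    out = img.copy()
    if noise.rms > 0:
        out += rng.normal(0.0, noise.rms, img.shape)
    if noise.line_drift != 0:
        out += (np.arange(img.shape[0]) * noise.line_drift)[:, None]
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# Image measurements
# ---------------------------------------------------------------------------

def cross_section(topo: Topograph, p0: tuple[float, float],
                  p1: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear height profile along the segment p0 -> p1 (nm coordinates),
    sampled at pixel_size steps.  Returns (distance_nm, height_nm)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        raise ValueError("degenerate zero-length section line")
    x_ext, y_ext = topo.extent
    for p in (p0, p1):
        if not (0 <= p[0] <= x_ext and 0 <= p[1] <= y_ext):
            raise ValueError("section endpoints must lie inside the image")
    n = max(int(np.floor(length / topo.pixel_size)) + 1, 2)
    t = np.linspace(0.0, length, n)
    pts = p0 + (p1 - p0)[None, :] * (t / length)[:, None]
    # pixel centres sit at (index + 0.5) * pixel_size
    cols = pts[:, 0] / topo.pixel_size - 0.5
    rows = pts[:, 1] / topo.pixel_size - 0.5
    h = ndimage.map_coordinates(topo.heights, [rows, cols], order=1,
                                mode="nearest")
    return t, h


def axis_profile(topo: Topograph, y: float, x_range: tuple[float, float]
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: cross-section parallel to the x (scan) axis."""
    return cross_section(topo, (x_range[0], y), (x_range[1], y))


def height_timetrace(frames, point: tuple[float, float], window: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Median height in a square window (side ``window`` nm) centred at
    ``point``, for every frame.  Returns (time_s, height_nm)."""
    times, heights = [], []
    for f in frames:
        half = 0.5 * window / f.pixel_size
        col = point[0] / f.pixel_size - 0.5
        row = point[1] / f.pixel_size - 0.5
        ny, nx = f.heights.shape
        if window > min(f.extent):
            raise ValueError("window larger than the image")
        if not (0 <= col < nx and 0 <= row < ny):
            raise ValueError("point outside the image")
        r0 = max(int(np.floor(row - half)), 0)
        r1 = min(int(np.ceil(row + half)) + 1, ny)
        c0 = max(int(np.floor(col - half)), 0)
        c1 = min(int(np.ceil(col + half)) + 1, nx)
        times.append(f.timestamp)
        heights.append(float(np.median(f.heights[r0:r1, c0:c1])))
    return np.asarray(times), np.asarray(heights)


# ---------------------------------------------------------------------------
# Disassembly emulation
# ---------------------------------------------------------------------------

def emulate_disassembly(spec: RibbonGeometrySpec, removal_schedule,
                        tip: TipModel = TipModel(),
                        noise: NoiseModel = NO_NOISE,
                        fps: float = 1.0, n_frames: int | None = None,
                        pixel_size: float = 1.0, seed: int = 0
                        ) -> list[Topograph]:
    """Layer-by-layer acid disassembly of a uniform layered ribbon.

    At each scheduled time the current top molecular layer is removed; its
    molecules do not vanish but are laid down flat on the substrate flanking
    the ribbon footprint (alternating sides, with seeded jitter), mirroring
    the observation that detached molecules stay near the ribbon.  Frames are
    rendered at ``fps`` until ``n_frames`` (default: just past the last
    event).
    """
    if spec.layers < 2:
        raise ValueError("need at least 2 layers to disassemble")
    removal_schedule = sorted(float(t) for t in removal_schedule)
    if n_frames is None:
        last = removal_schedule[-1] if removal_schedule else 0.0
        n_frames = int(np.ceil(last * fps)) + 3
    if removal_schedule and removal_schedule[-1] > (n_frames - 1) / fps:
        raise ValueError("removal scheduled after the end of the sequence")

    d = spec.molecule_diameter
    r = 0.5 * d
    x0 = 10.0
    y0 = 10.0 + spec.ribbon_width  # leave room on both sides for debris
    length = spec.n_periods * spec.stagger
    layers = [layered_ribbon_primitives(spec, x0=x0, y0=y0, layers=1)
              for _ in range(spec.layers)]
    for k, layer in enumerate(layers):
        layers[k] = [dataclasses.replace(c, zc=c.zc + k * d) for c in layer]

    rng = np.random.default_rng(seed)
    debris: list[CylinderX] = []
    side, slot = 1, 0

    extent = (length + x0 + 20.0, 2 * y0 + spec.ribbon_width + 10.0)
    frames: list[Topograph] = []
    events = list(removal_schedule)
    for i in range(n_frames):
        t = i / fps
        while events and t >= events[0]:
            events.pop(0)
            if len(layers) > 1:
                removed = layers.pop()
                for cyl in removed:
                    slot_y = (y0 - (slot // 2 + 1) * 1.2 * d if side < 0
                              else y0 + spec.ribbon_width + (slot // 2 + 1) * 1.2 * d)
                    jitter = rng.uniform(-0.2 * d, 0.2 * d)
                    debris.append(dataclasses.replace(
                        cyl, yc=slot_y + jitter, zc=r))
                    side, slot = -side, slot + 1
        prims = [c for layer in layers for c in layer] + debris
        fnoise = dataclasses.replace(noise, seed=noise.seed + i) \
            if (noise.rms or noise.line_drift) else noise
        frames.append(render_primitives(prims, tip, pixel_size, extent,
                                        fnoise, oversample=2,
                                        timestamp=t, frame_index=i))
    return frames


# ---------------------------------------------------------------------------
# TIFF export
# ---------------------------------------------------------------------------

def write_tiff_stack(frames, path) -> None:
    """32-bit float TIFF stack with the pixel size recorded both in the TIFF
    resolution tag (pixels per cm) and in the image description metadata."""
    import tifffile

    stack = np.stack([f.heights for f in frames]).astype(np.float32)
    px = frames[0].pixel_size          # nm / pixel
    px_per_cm = 1e7 / px
    tifffile.imwrite(
        path, stack, photometric="minisblack",
        resolution=(px_per_cm, px_per_cm), resolutionunit=3,
        metadata={"pixel_size_nm": px, "axes": "TYX",
                  "timestamps_s": [f.timestamp for f in frames]})
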