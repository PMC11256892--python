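# Methods

`colribbon` models the pH-controlled disassembly and reassembly of collagen
nanoribbons on a charged mineral substrate, and re-implements the analysis
and imaging chain that such an experiment uses: backbone mass profiles and
their Fourier spectra (the D-band), synthetic high-speed AFM topographs, and
tapping-mode force estimation. This note records the model, its assumptions,
the defaults and why they were chosen, and what the synthetic data can and
cannot show.

## Coarse-grained molecule model

A collagen molecule (~300 nm x 1.5 nm triple helix) is represented as a
flexible bead-spring rod. Beads are spheres of diameter 1.5 nm — the
measured height of a single molecule on the substrate — spaced 1.5 nm along
the contour, joined by harmonic bonds (default 60 kT/nm²) and a harmonic
bending term about the straight configuration (default 20 kT/rad²,
a semiflexible rod at these scales). Energies are in units of kT at 300 K;
lengths in nm.

Charges sit on a subset of beads. Each charge site is acidic
(aspartate/glutamate-like, pKa 4.2), basic (lysine/arginine-like, pKa 10.5,
or histidine-like, pKa 6.0) or permanently neutral. Charge states are
discrete (−1/0/+1): an acidic site carries −1 iff pH > pKa, a basic site +1
iff pH < pKa, and a site at pH = pKa exactly is neutral (tie broken toward
zero). This deterministic rounding of the Henderson–Hasselbalch occupancy
matches the binary switch the mechanism needs — at pH 7.4 the rod is
amphoteric; at pH 2.2 every negative charge is removed and the
histidine-like sites add positives. Fractional charge regulation is
deliberately not modelled.

The real collagen charge sequence is not resolved at this coarse-graining;
the default rod (30 beads) tiles a 10-bead motif — three basic, spacer,
three acidic, one histidine-like, two spacers — chosen to reproduce the
qualitative titration behaviour. Motif, pKa table and bead counts are all
user-facing configuration.

## Interactions

* **Screened electrostatics** between charged beads: Debye–Hückel,
  `u(r) = lB·q1·q2·exp(−r/λD)/r`, cut and shifted at the cutoff (≥ 3λD).
  The default screening length is 1.5 nm and the default coupling
  lB = 7 nm. The coupling is an *effective* Bjerrum length: each charged
  bead lumps several residue charges, so bead–bead coupling exceeds the
  bare aqueous value (0.71 nm). These two defaults are the model
  calibration: they are set so that the neutral-pH amphoteric rods bind
  with a few kT per rod-contact (stable ribbon at 300 K) while the
  all-cationic acid-pH rods unbind — the regime the mechanism requires.
  `debye_length(BufferSpec)` converts a real electrolyte to λD (the
  experimental PBS + 300 mM KCl buffer gives 0.46 nm).
* **Nonspecific attraction**: 12-6 Lennard-Jones, σ = bead diameter,
  ε = 0.15 kT (0.25 kT in the generic defaults), cut and shifted at 2.5σ.
  The shift makes the energy continuous at the cutoff; the resulting force
  discontinuity there is accepted, as usual for overdamped dynamics.
  ε is kept below the electrostatic binding scale so that assembly is
  charge-driven, not van-der-Waals-driven: under acid the LJ attraction
  alone must not hold the ribbon together.
* **Substrate**: the plane z = 0 is negatively charged (mica-like), so a
  bead of charge q has energy `−A·q·exp(−z/δ)` (default A = 2 kT,
  δ = 1 nm): positive beads are attracted, negative beads repelled by the
  same form. This produces the "memory effect": under acid the
  all-cationic molecules stay pinned near the ribbon footprint, ready to
  reassemble. Hard exclusion below the bead radius is kinematic (reflecting
  wall), not energetic.

## Dynamics

Overdamped (Brownian) Langevin dynamics, first-order Euler–Maruyama:
`x ← x + (F/γ)dt + sqrt(2 kT dt/γ)·η`, with γ = 1 per bead, periodic x/y
boundaries and reflecting walls at the bead radius and at the top of a thin
slab (quasi-2D: the experiment is on a plane, but detachment and re-landing
are part of the mechanism). Time is reported in reduced units
(γ·nm²/kT); no mapping to seconds is attempted because the friction of the
real system is not calibrated.

Numerical choices:

* dt = 2×10⁻³ reduced units. The 12-6 core is stiff compared with any
  affordable Euler step, so per-bead displacements are clamped to 0.1 nm
  (a trust-region step, standard for stiff excluded-volume cores). The
  clamp engages only in rare deep-compression events, preserves the descent
  direction at T = 0, and can be disabled (`max_move=None`), in which case
  a step larger than half a bead diameter aborts with "timestep too large".
* Nonbonded pairs come from a periodic k-d tree with a 0.9 nm Verlet skin,
  rebuilt only when a bead has drifted half a skin; directly bonded
  neighbours are excluded from nonbonded sums. The accelerated path is
  tested to agree with an O(N²) double loop to 1e−9.
* One named RNG per run (NumPy PCG64); the seed is part of the run
  configuration and recorded in trajectory metadata, and identical
  seed + config reproduces trajectories byte-for-byte.

A pH protocol is an ordered (time, pH) schedule; at each switch the discrete
site charges of every rod are reassigned and integration continues.

## Ribbon construction and the demo pH cycle

`build_ribbon_state` lays molecules in the five-row staggered arrangement:
molecule j starts at axial position j·D and occupies lateral row j mod 5, so
a molecule and its fifth successor leave the axial gap 5D − L. With
L = 4.48·D this is the canonical collagen packing: overlap regions (five
molecules deep, length L − 4D = 0.48D) alternate with gap regions (four
deep, 0.52D), planting a mass modulation of period D. With 300 nm molecules
D = 67 nm — the D-band.

The pH-cycle study conditions (the package's defaults in `RunConfig`) use a
deliberately small system — one fibril of six 10-bead molecules (60 beads)
in a 30×30×5 nm slab, stagger 3 nm — integrated for 2×10⁵ steps with the
protocol neutral (t < 60) → pH 2.2 (60–100) → neutral (100–400). These sizes
are chosen so a five-seed ensemble completes in minutes on one CPU while
still showing the full mechanism: largest-cluster mass fraction 1.0 at
neutral pH, collapse toward ~0.5–0.7 within 10^4 steps of the acid switch, recovery at neutral pH. The
80%-recovery criterion and the analysis windows are configuration values,
not physics.

## Structure analysis

* **Clustering**: single-linkage over rods; two rods are connected iff any
  inter-rod bead pair is within 1.5 bead diameters (contact semantics,
  matching how "assembled" is read off an image).
* **Backbone**: beads of an elongated cluster (principal-axis anisotropy
  ≥ 2) are ordered by projection on the first principal axis and a
  smoothing spline is fitted per coordinate; non-elongated clusters fall
  back to a straight principal-axis profile.
* **Mass profile**: bead count per arclength bin (default bin = bead
  spacing); counts are conserved exactly. Height profiles from topographs
  share the same container with a `source` tag.
* **Periodogram**: mean removal, Hann window, FFT. The windowed signal is
  rescaled to the energy of the unwindowed residual so Parseval holds
  exactly (one-sided power sums to N·variance); this affects no peak
  position. Dominant-period estimation takes the power maximum in a period
  band and refines it by three-point parabolic interpolation.
* **Similarity**: maximum normalised circular cross-correlation of the
  mean-removed profiles over all lags (alignment-invariant, 1 for identical
  shapes), with a bin-permutation null (default 500 shuffles) for
  significance.

## Synthetic AFM

The sample (bead configurations, cylinders, or a parametric D-banded
ribbon slab with gap/overlap plateau heights 3.5/4.5 nm) is rasterised into
a height field on a grid oversampled 2–4× relative to the output pixel,
then dilated with a spherical tip (default radius 2 nm — sub-molecular
detail is visible in the experiment, implying a sharp tip): the image at
each pixel is the highest tip-apex position at which the tip ball still
touches the sample, i.e. grayscale morphological dilation with the
structuring element `sqrt(Rt²−d²)−Rt`. Rendered heights therefore bound the
true heights from above, with equality on flat regions wider than the tip.
Gaussian pixel noise (default 0.1 nm rms in noisy mode) and an optional
deterministic per-line height creep are added afterwards; the default
cadence is 1 frame/s and the default frame format follows the experiment's
512×256 at ~1 nm/pixel.

Layer pitch: measured heights of molecule/fibril/ribbon are integer-ish
multiples of the 1.5 nm molecule diameter (1.5 / 3.0 nm), which is
consistent with vertically commensurate stacking rather than hexagonal
close packing (a groove-nested second layer would sit at 2.05 nm, apex
2.8 nm). The renderer therefore stacks layers at one molecule diameter by
default; the five-molecule fibril (three molecules in the bottom layer, two
nested laterally above) images at a 3.0 nm apex. An optional compressed
layer pitch reproduces sub-nominal steps (the measured disassembly step is
~1.3 nm vs the nominal 1.5 nm); the emulator takes no position on which the
instrument saw.

The disassembly emulator removes the top molecular layer at scheduled
times; removed molecules are laid flat beside the ribbon footprint
(detached molecules remain substrate-bound near the ribbon), so the imaged
footprint never shrinks while the apex height drops by one molecule
diameter per event.

## Tapping-mode force estimation

The cantilever is its fundamental eigenmode: a point mass m = k/ω₀² driven
at resonance with drive amplitude F₀ = kA₀/Q (mechanical excitation), with
quality factor Q and a DMT tip–sample force: constant van-der-Waals
adhesion `−HR/6d²` outside contact (intermolecular distance a₀ = 0.165 nm)
and Hertz repulsion `(4/3)E*√R·δ^3/2` inside. Integration is fixed-step
RK4 at 1500 steps/cycle (results are step-independent below ~T/1000), 60
cycles of transient decay then 200 measured cycles; non-steady amplitudes
(beats) are flagged, never silently averaged. `setpoint_to_force` bisects
the cantilever rest height until the oscillation amplitude matches the
setpoint within 0.01 nm and reports the peak repulsive force per cycle —
the quantity quoted as the "peak force" of an imaging experiment.

Contact-parameter defaults: tip radius 2 nm, Hamaker 3 zJ, sample modulus
300 MPa (effective, hydrated collagen film range; at ~10 MPa the DMT
contact is adhesion-dominated and no repulsive peak exists, contrary to
the imaging regime), Poisson 0.3. With the experiment's cantilever
(522 kHz, 0.15 nN/nm, Q 1.4, A₀ 3.5 nm, Asp 3.2 nm) these defaults put the
peak force at a few hundred pN, the right scale for gentle protein
imaging; no quantitative match is claimed because tip radius and sample
stiffness of the real experiment are unknown. All parameters are exposed.

## What the synthetic data does and does not show

The generator emulates the geometry (stagger, D-band, layer heights), the
imaging physics (tip dilation, pixelation, noise) and the mechanism
(charge-switch driven assembly/disassembly on a substrate). It does not
emulate: real collagen sequence electrostatics, substrate lattice epitaxy
(the experimental fibrils align with the mica crystal axes), hydrodynamic
interactions, imaging feedback artifacts, or real time scales. Passing
tests therefore demonstrate the internal consistency of the model and
analysis chain and the qualitative mechanism, not quantitative agreement
with any particular specimen.

## Known limitations

* First-order Euler–Maruyama with a displacement clamp: near-contact
  statistics are approximate; equilibrium properties inside the clamped
  regime (≳ 3 kT compressions) are biased small.
* Discrete −1/0/+1 protonation; no charge regulation by local potential.
* The quasi-2D slab suppresses 3D escape; detachment kinetics are faster
  than in a half-space.
* Similarity of short profiles (few tens of bins) has a broad permutation
  null; significance claims need the seeded ensemble, not a single run.
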