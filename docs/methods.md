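# Methods

This note documents the models implemented in `necrotherm`, the parameter
choices that matter, the synthetic data world, and the numerical decisions
a user extending or auditing the package should know about.

## 1. Photon transport

A voxelized Monte Carlo random walk in a homogeneous block. Packets launch
uniformly over the beam disk, normal to the entry face; free paths are
exponential with μₜ = μₐ + μₛ; at every interaction the current voxel
absorbs the fraction μₐ/μₜ of the packet weight (implicit capture) and the
direction is redrawn from the Henyey–Greenstein phase function. Packets
leaving the block terminate (matched refractive indices: no Fresnel
reflection, no re-entry); packets below weight 10⁻⁴ play Russian roulette
with survival probability 0.1.

Bookkeeping choice: roulette conserves energy only in expectation, so the
net roulette residual (killed weight minus the boost given to survivors)
is folded into `escaped_fraction`. The ledger *deposited + escaped = 1*
then holds to float rounding on every run, which the tests assert at 1e-6.

Defaults: 20×20×20 mm block, 0.5 mm voxels (a compromise between Monte
Carlo counting noise and the thermal gradient scale; both are configurable),
10⁶ photons, porcine-liver optics at 750 nm (μₐ = 0.1 /mm, μₛ = 6.14 /mm,
g = 0.9), 5 mm beam. Voxel centers sit at (i + ½)·Δx with z = 0 at the
irradiated face. The normalized energy density is written/read as a
four-column CSV (x, y, z, value) with grid metadata in `#` header comments.

## 2. Bioheat solver

The Pennes equation for stationary perfused tissue (the advective term is
identically zero for tissue that does not move):

ρcₚ ∂T/∂t = ∇·(k∇T) + Q + ρ_b c_b ω_b (T_b − T), with Q_met = 0.

* **Discretization**: uniform-grid explicit FTCS. The stability bound
  (7-point Laplacian + perfusion + Robin terms) is computed from the
  material properties and enforced; an unstable Δt raises an error naming
  the bound. At the default 0.5 mm / 0.1 s the scheme is stable with a
  factor ≈3 margin.
* **Boundaries**: the irradiated (z⁻) face uses a ghost-node Robin
  condition −k ∂T/∂n = h(T − T_amb); the five other faces hold a fixed
  temperature imposed at the cell boundary by ghost reflection.
* **Source modes**: a 5 ns pulse at 10 Hz raises the surface adiabatically
  by μₐF/(ρcₚ) ≈ 0.097 K (371.79 mJ/cm²) — far below a kelvin — so the
  default source applies the time-averaged power (pulse energy × rate)
  continuously. The pulsed (square-wave-gated peak power) mode exists and
  is verified against the average mode over short horizons; both deposit
  identical energy per period by construction.
* **Thermal properties**: constant literature liver values ρ = 1079 kg/m³,
  cₚ = 3540 J/(kg·K), k = 0.52 W/(m·K). All three accept callables of
  temperature for users who want temperature-dependent curves; the solver
  then re-evaluates them each step.
* **Free convection**: h is physically 5–25 W/(m²·K) for a liver surface
  exposed to still air but is never known precisely; `calibrate_h_conv`
  anchors it to a measured or published plateau temperature by monotone
  root finding, clamping at the range ends. This calibration is the
  supported way to pin the model to a specific experiment.
* **Probe**: the voxel at the center of the irradiated face (beam axis,
  first voxel layer), initial and far-boundary temperature 293.15 K (an
  exposed liver equilibrates toward ambient during laparotomy).

Known limitation: with constant properties the steady solution is linear
in source power about the no-laser baseline (the baseline itself sits a
few kelvin above ambient because perfusion pulls the block toward blood
temperature). Published liver measurements show a mildly super-linear
power dependence, attributable to temperature-dependent ρ, cₚ, k; with
constant defaults the model reproduces the 73 mJ plateau to ≈2.4 K at the
weakest in-range convection and the 30 mJ plateau to ≈2.1 K, while
necrosis percentages land within ≈5 points of published values. Users who
need tighter plateau agreement should supply property curves via the
callable hook.

## 3. Damage kinetics

dα/dt = (1 − α)ⁿ A exp(−ΔE/(RT)), α(0) = 0, with liver constants
A = 5.51×10⁴¹ s⁻¹, ΔE = 2.77×10⁵ J/mol, n = 3 (empirical; configurable),
R = 8.314 J/(mol·K). The exponent is the standard negative Arrhenius form:
a positive exponent with these constants would give physically meaningless
rates (~e²⁰⁰ s⁻¹), while the negative form gives 2.2×10⁻² s⁻¹ near 333 K,
the regime in which liver damage accumulates over minutes.

Integration is RK4 along the linearly interpolated temperature trace; the
step is halved until the α trajectory changes by < 10⁻⁴, and the
constant-temperature closed forms (n = 1: 1 − e^{−kt};
n = 3: 1 − (1 + 2kt)^{−1/2}) are reproduced to that tolerance in tests.
(1 − α) is floored at zero inside the integrator so α is monotone and
bounded for any temperature history. Damage is evaluated at the surface
probe only; θ_d = clamp(α, 0, 1) and the reported percentage is 100·θ_d.

Useful sensitivity: near 333 K a +1 K shift multiplies the rate by
exp(ΔE/RT²) ≈ e^{0.30} ≈ 1.35 — necrosis predictions inherit roughly 30 %
per kelvin of plateau error, which is why the percentage anchors are
looser than the temperature anchors.

## 4. Histology quantification

* **Mosaic planning**: starting from one tile, the mosaic count doubles
  along the dimension with the larger tile extent (ties double columns)
  until tile_w × tile_h × 4 bytes ≤ 4 MiB. This rule is a reconstruction
  from the three published whole-slide decompositions (1024, 8192, 16384
  tiles with tile sizes 960×968, 1200×638, 810×792), all of which it
  reproduces; it is not a published algorithm. Splitting/stitching is
  lossless with row-major tile order and truncated edge tiles.
* **Segmentation** is a pluggable interface: any callable mapping an RGB
  tile to a label raster. The classical default thresholds the mean
  channel with Otsu (stained cells are darker than the near-white
  background), fills holes, splits touching cells by distance-transform
  watershed and drops objects outside a 3–20 µm equivalent-diameter band.
  A trained neural segmenter can be dropped in without touching the rest
  of the pipeline; no segmentation-quality metrics of any external network
  are reproduced here.
* **Classification** applies the RGB boxes to the per-cell *mean* RGB
  (robust to edge antialiasing and stain texture). The brown and blue
  boxes are disjoint by their G ranges; cells in neither box are excluded
  from all areas.
* **Patch statistics**: non-overlapping 200 µm patches anchored at the
  raster origin; cells contribute their whole area to the patch containing
  their centroid; edge patches are truncated and use their true area in ρ.
  Patches with no classified area have undefined Γ and score 0 % (the
  artifact filter, not the score, is responsible for isolating the lesion).
* **Artifact filter**: necrosis maps are quadrimodal in practice
  (background / low / intermediate / high), so maps are binarized at the
  second of three Otsu thresholds (256-bin histogram of values scaled to
  [0, 255]; deterministic). Stage 1 averages the registered maps of a
  stack and keeps the connected component containing the global maximum;
  its centroid seeds stage 2, which per map discards components with
  solidity < 0.6 and keeps the survivor nearest the stage-1 centroid.
  When nothing survives the map is zeroed and flagged rather than failing.

## 5. Registration and volumetry

Rigid transforms (rotation about the raster center + translation) are
estimated by a coarse-to-fine rotation scan (1° then 0.1° steps over
±12°), scoring each candidate by the peak of the plain FFT
cross-correlation of the two feature images and refining the shift to
1/20 px with an upsampled DFT. The feature image is the lightly smoothed
L\*a\*b\* a\* channel: DAB-brown is strongly positive, hematoxylin-blue
negative, so both the lesion's brown boundary ring and the surrounding
tissue texture contribute. Plain correlation was chosen over phase
correlation deliberately: whitening the spectrum weights all frequencies
equally, which makes the estimator lock onto the uncorrelated cell-scale
content of neighboring sections; un-whitened correlation degrades
gracefully when only part of the content is shared.

Stacks register pairwise outward from a reference in the middle of the
stack (registering from the first section skews the reconstruction);
composed transforms carry each necrosis map into the reference frame with
bilinear resampling (values clipped to [0, 100]; translations rescale from
section pixels to patch units). Depth interpolation is linear from the
40 µm section spacing to a 4 µm step, acting on continuous necrosis values
(mask interpolation is a special case and stair-steps). Metrics count
voxels/patches above a threshold (default > 0; configurable — use ≈50 for
half-max support of binary-like maps, since bilinear feathering widens
strictly-positive support): volume = count × patch² × step, area per depth
= count × patch area, percent per depth = mean over counted patches (an
implementation choice; a median or maximum reduction would also be
defensible).

## 6. The synthetic world

`synth` renders what a cleaved Caspase-3 IHC section of a laser lesion
looks like schematically: blue cells everywhere (2000 /mm² outside,
600 /mm² inside the lesion — cell death lowers density), a dense brown
ring at the lesion boundary (1500 /mm², 30–80 µm wide), sparse brown cells
inside falling inversely with irradiation time (d(t) = 300 /mm² · 1 min/t),
and — important for filter behaviour — sparse background apoptotic cells
(150 /mm², a few percent of cells) so background patches score below the
lesion's 100 % ceiling, as real slides do. Cell colors are drawn uniformly
inside the classification boxes, jittered (σ = 3 by default) and clipped,
so classifiability is guaranteed at zero jitter and stressed above it.
Cells are anti-aliased disks of 2.5–5 µm radius with overlap thinning.

For serial stacks the healthy-tissue field is drawn **once** and shared by
all sections, with only the lesion content redrawn per section: serial
sections 4–40 µm apart traverse the same tissue, and without that shared
structure rigid rotation would be fundamentally unidentifiable (the only
common feature, the ring, is rotationally symmetric). Per-section rigid
jitter is applied to the geometry (exactly, not by resampling) and
recorded as ground truth; lesion radius can grow linearly with depth to
emulate sample curvature, and the analytic lesion volume ∫πr(z)²dz is
returned.

What a green test on these fixtures establishes: the pipeline arithmetic,
geometry handling, filtering logic and registration recovery are correct.
What it does not establish: robustness to real stain variability, scanner
noise, tissue folds, or segmentation of densely clumped nuclei — the
fixtures are schematic by design and contain none of these.

## 7. Numerical details and edge cases

* Monte Carlo runs are bit-reproducible for fixed seed, photon count and
  batch size (PCG64; batched vectorized implementation).
* `plateau_temperature` averages the trailing window and flags
  non-convergence when the trailing slope exceeds 0.01 K/min.
* Multilevel Otsu requires at least n+1 distinct values; constant maps
  raise a degenerate-histogram error (stage 2 converts this into an
  all-zero, flagged result).
* The mosaic rule, classification boxes, patch size, decay constant
  k = 100, solidity cutoff 0.6, section spacing 40 µm and depth step 4 µm
  are all configurable; the defaults are the published protocol.
* Phase annotations on heating curves use 315.15 K (enzyme-inactivation
  threshold) for the end of the fast-rise phase and proximity to the
  plateau (±0.3 K) for the end of the slow-rise phase.
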