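# necrotherm

Predicting and measuring laser-induced necrosis in liver tissue.

Photoacoustic imaging and other laser-based interventions deliver pulsed
near-infrared light to internal organs for which no laser-safety standard
exists (the regulatory maximum permissible exposure covers only skin and
eyes). The operational safety question is whether a given protocol — pulse
energy, beam diameter, repetition rate, exposure time — produces thermal
necrosis in the target tissue. `necrotherm` provides both halves of the
answer for perfused liver:

* **a forward simulation chain** that predicts the percentage of necrotic
  tissue at the irradiated surface, and
* **a quantitative histology chain** that measures necrosis from digitized
  cleaved Caspase-3 immunohistochemistry (IHC) sections, replacing
  subjective categorical grading, and reconstructs the lesion in 3-D from
  serial sections.

A synthetic-fixture module generates IHC-like sections and section stacks
with exact ground truth so that every pipeline stage is testable without
animal data.

## The models

**Photon transport.** A flat-top disk beam enters a homogeneous
20×20×20 mm tissue block. Photon packets follow the standard voxel Monte
Carlo scheme: exponential free paths with attenuation μₜ = μₐ + μₛ,
implicit capture (a fraction μₐ/μₜ of the packet weight absorbed per
interaction), Henyey–Greenstein scattering with anisotropy g, and Russian
roulette. Defaults are porcine liver at 750 nm: μₐ = 0.1 mm⁻¹,
μₛ = 6.14 mm⁻¹, g = 0.9. The output is the normalized absorbed-energy
density D(𝐫) (fraction of launched energy per m³).

**Bioheat.** Tissue temperature follows the Pennes equation

    ρ cₚ ∂T/∂t = ∇·(k ∇T) + Q + ρ_b c_b ω_b (T_b − T),    Q = P · D(𝐫) · ONOFF(t)

with blood perfusion ω_b = 0.0175 s⁻¹, c_b = 3617 J/(kg·K),
ρ_b = 1050 kg/m³, T_b = 310.15 K, free convection on the irradiated face
and fixed temperatures on the other five. Because the single-pulse
adiabatic temperature rise is ≈0.1 K, the nanosecond pulse train is
replaced by its time-averaged power by default (the pulsed mode is kept
for verification). The solver is an explicit finite-difference scheme with
an enforced stability bound.

**Damage kinetics.** The degree of injury α accumulates along the probe
temperature trace by the Arrhenius model

    dα/dt = (1 − α)ⁿ · A · exp(−ΔE / (R T(t))),    n = 3,
    A = 5.51×10⁴¹ s⁻¹,  ΔE = 2.77×10⁵ J/mol,

and the necrotic fraction is θ_d = min(max(α, 0), 1); ×100 gives the
reported necrosis percentage.

**Histology scoring.** Segmented cells are classified by mean RGB into
DAB-brown (60 ≤ R ≤ 210, G ≤ 151, B ≤ 130) or hematoxylin-blue
(150 ≤ R ≤ 186, G ≥ 155, B ≥ 160). Per 200 µm × 200 µm patch,

    necrosis % = Γ · e^(−k·ρ) · 100,    k = 100,
    Γ = blue area / (blue + brown area),  ρ = brown area / patch area.

A two-stage artifact filter (multilevel Otsu binarization, connected
components, solidity ≥ 0.6, nearest-centroid selection) isolates the
lesion; rigid registration, 40 µm → 4 µm linear depth interpolation and
counting metrics produce lesion volume, area-vs-depth and
percent-vs-depth profiles.

## Worked example

```python
from necrotherm.config import SimulationConfig
from necrotherm.damage import predict_necrosis
from necrotherm.optics import VoxelGrid

cfg = SimulationConfig(
    grid=VoxelGrid(extent=(20.0, 20.0, 20.0), voxel_size=1.0),
    cases=[(0.073, 600.0)],          # 73 mJ pulses at 10 Hz, 10 minutes
    n_photons=200_000, seed=0, dt=0.4,
)
report = predict_necrosis(cfg)[0]
print(f"plateau temperature : {report['plateau_K']:.2f} K")
print(f"necrosis prediction : {report['necrosis_percent']:.2f} %")
```

prints (coarse 1 mm demo grid; the full-resolution run uses 0.5 mm voxels
and 10⁶ photons):

```
plateau temperature : 329.68 K
necrosis prediction : 64.72 %
```

i.e. ten minutes of 73 mJ irradiation drives the surface to a ≈330 K
plateau and past the damage threshold — a protocol to avoid. The histology
chain, run on a synthetic section with known ground truth:

```python
from necrotherm.histoquant import quantify_section, stage1_centroid, stage2_filter
from necrotherm.synth import SynthSectionParams, gen_section

params = SynthSectionParams(width_px=1200, height_px=1200, um_per_px=1.0,
                            region_radius_um=300.0, ring_width_um=80.0, seed=7)
section, truth, cells = gen_section(params)
nmap, measured = quantify_section(section)
```

segments 2603 cells, reproduces the ground-truth necrosis map with a mean
absolute patch error of 6.0 percentage points, and the artifact filter
keeps exactly the four fully necrotic lesion patches (mean 100 %).

## Command line

Every stage is also a `necrotherm` subcommand operating on text formats
(YAML configs, CSV grids/traces, PNG/TIFF rasters):

```sh
necrotherm mc --config cfg.yaml --out density.csv --photons 1000000 --seed 1
necrotherm bioheat --density density.csv --config cfg.yaml --out trace.csv
necrotherm damage --trace trace.csv --config cfg.yaml
necrotherm simulate --config cfg.yaml --out report.json
necrotherm quantify --sections sections/ --meta meta.yaml --out maps/
necrotherm reconstruct --maps maps/ --meta meta.yaml --out volume/
necrotherm synth section --seed 1 --out fixtures/
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's reference quantities from
scratch: the patch-model ceiling for a blue-only patch, the power-of-two
mosaic decompositions of two published whole-slide sizes, and — via the
full Monte Carlo → bioheat → damage chain at 10⁶ photons, 0.5 mm voxels
and 0.1 s steps, with the free-convection coefficient calibrated within
5–25 W/(m²·K) against the published 73 mJ plateau — the steady plateau
temperatures at 73 and 30 mJ and the necrosis percentages at 73 mJ/20 min,
30 mJ/20 min and 73 mJ/10 min. Run it as

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(≈2 minutes on one CPU). See `docs/methods.md` for model assumptions,
parameter choices and known limitations.
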