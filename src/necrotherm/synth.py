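"""Synthetic IHC-like fixtures with machine-readable ground truth.

Real validation data for this pipeline are serial IHC sections of
laser-irradiated liver; none ship with the package.  The generator emulates
the four qualitative features such sections show: hematoxylin-blue cells
everywhere, a DAB-brown cell ring hugging the boundary of the circular
irradiated region, reduced cell density inside the region, and sparse brown
cells inside it whose density falls with irradiation time (severity).

Every generated object carries its ground truth: the exact cell table
(position, radius, class), the necrosis map computed analytically from that
table with the same patch equations the measurement pipeline uses, and — for
stacks — the per-section rigid jitter and the analytic lesion volume.  The
fixtures are schematic by design: disks with class-consistent colors on a
light background, no scanner noise model, no real stain texture.  A test
that passes on them validates the pipeline arithmetic and geometry, not
robustness to real histology variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from necrotherm.bioheat import TemperatureTrace
from necrotherm.errors import InvalidParameterError
from necrotherm.histoquant import (CellClassRules, NecrosisMap, SectionImage,
                                   necrosis_map, patch_fractions)
from necrotherm.volumetry import RigidTransform

__all__ = [
    "SynthSectionParams", "SynthTraceParams", "gen_section", "gen_stack",
    "gen_temperature_trace", "inside_brown_density_for_time",
]

#: Background color of a rendered slide (near-white, slightly warm).
BACKGROUND_RGB = (243.0, 242.0, 238.0)


def inside_brown_density_for_time(irradiation_min: float,
                                  reference_density_per_mm2: float = 300.0,
                                  reference_min: float = 1.0) -> float:
    """Brown-cell density inside the lesion as a function of exposure time.

    The observed density is inversely proportional to the irradiation time;
    this maps that statement onto ``d(t) = d_ref * t_ref / t`` with the
    reference anchored at 1 minute (minimal damage: many surviving
    apoptotic cells inside the region).
    """
    if irradiation_min <= 0:
        raise InvalidParameterError("irradiation time must be positive")
    return reference_density_per_mm2 * reference_min / irradiation_min


@dataclass
class SynthSectionParams:
    """Geometry, densities and colors of one synthetic IHC section.

    Densities are cells/mm^2; the defaults put ~80 cells in a 200-um patch
    outside the lesion (consistent with 5-10 um cells at realistic liver
    cellularity) and a third of that inside.
    """

    width_px: int = 1200
    height_px: int = 1200
    um_per_px: float = 0.23
    region_center_um: tuple[float, float] | None = None  # (x, y); None=center
    region_radius_um: float = 80.0
    ring_width_um: float = 30.0
    cell_radius_um: tuple[float, float] = (2.5, 5.0)
    outside_density: float = 2000.0   # blue cells/mm^2 outside the lesion
    inside_density: float = 600.0     # blue cells/mm^2 inside the lesion
    ring_brown_density: float = 1500.0  # brown cells/mm^2 in the ring
    inside_brown_density: float = 0.0   # brown cells/mm^2 inside (severity)
    #: Sparse apoptotic cells scattered through healthy tissue (~6 per
    #: patch, a few percent of all cells); keeps background patch scores
    #: strictly below a fully necrotic lesion's 100%, as on real slides.
    outside_brown_density: float = 150.0  # brown cells/mm^2 outside
    color_jitter_sd: float = 3.0
    seed: int = 0
    patch_um: float = 200.0

    def __post_init__(self) -> None:
        if min(self.outside_density, self.inside_density,
               self.ring_brown_density, self.inside_brown_density,
               self.outside_brown_density) < 0:
            raise InvalidParameterError("densities must be >= 0")
        if self.inside_density >= self.outside_density:
            raise InvalidParameterError(
                "inside cell density must be below the outside density")


def _sample_in_region(rng, n, width_um, height_um, predicate):
    """Rejection-sample n points (x, y in um) satisfying ``predicate``."""
    pts = np.empty((0, 2))
    while len(pts) < n:
        cand = rng.random((max(4 * n, 64), 2)) * [width_um, height_um]
        cand = cand[predicate(cand)]
        pts = np.vstack([pts, cand])
    return pts[:n]


def _box_color(rng, cls: str, rules: CellClassRules,
               jitter_sd: float) -> np.ndarray:
    """Draw a color uniformly inside the class box, then jitter + clip.

    At zero jitter every cell is classifiable by construction; larger
    jitter stresses classification robustness.
    """
    if cls == "brown":
        lo = np.array([rules.brown_r[0], 40.0, 30.0])
        hi = np.array([rules.brown_r[1], rules.brown_g_max,
                       rules.brown_b_max])
    else:
        lo = np.array([rules.blue_r[0], rules.blue_g_min, rules.blue_b_min])
        hi = np.array([rules.blue_r[1], 230.0, 235.0])
    c = lo + rng.random(3) * (hi - lo)
    c = c + rng.normal(0.0, jitter_sd, 3)
    return np.clip(c, lo, hi)


def _render_cells(canvas: np.ndarray, cells: pd.DataFrame,
                  um_per_px: float) -> None:
    """Paint anti-aliased disks onto the canvas, in place."""
    h, w = canvas.shape[:2]
    for row in cells.itertuples():
        r_px = row.radius_um / um_per_px
        cy, cx = row.centroid_row, row.centroid_col
        y0, y1 = int(max(0, np.floor(cy - r_px - 1))), \
            int(min(h, np.ceil(cy + r_px + 2)))
        x0, x1 = int(max(0, np.floor(cx - r_px - 1))), \
            int(min(w, np.ceil(cx + r_px + 2)))
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        alpha = np.clip(r_px + 0.5 - d, 0.0, 1.0)[:, :, None]
        color = np.array([row.r_color, row.g_color, row.b_color])
        canvas[y0:y1, x0:x1] = (alpha * color
                                + (1.0 - alpha) * canvas[y0:y1, x0:x1])


def _thin_overlaps(pts: np.ndarray, min_sep_um: float) -> np.ndarray:
    """Greedily drop one point of every too-close pair."""
    if len(pts) < 2:
        return np.ones(len(pts), dtype=bool)
    tree = cKDTree(pts)
    keep = np.ones(len(pts), dtype=bool)
    for i, j in sorted(tree.query_pairs(min_sep_um)):
        if keep[i] and keep[j]:
            keep[j] = False
    return keep


def _lesion_center_um(params: SynthSectionParams) -> tuple[float, float]:
    if params.region_center_um is not None:
        return params.region_center_um
    return (params.width_px * params.um_per_px / 2.0,
            params.height_px * params.um_per_px / 2.0)


def _field(rng, n, w_um, h_um, predicate, cls, params,
           rules) -> pd.DataFrame:
    """One cell population: positions, radii and colors in um coordinates."""
    xy = _sample_in_region(rng, n, w_um, h_um, predicate)
    radius = rng.uniform(*params.cell_radius_um, size=n)
    colors = np.array([_box_color(rng, cls, rules, params.color_jitter_sd)
                       for _ in range(n)]) if n else np.empty((0, 3))
    return pd.DataFrame({
        "x_um": xy[:, 0], "y_um": xy[:, 1], "radius_um": radius,
        "cell_class": cls,
        "r_color": colors[:, 0] if n else [],
        "g_color": colors[:, 1] if n else [],
        "b_color": colors[:, 2] if n else [],
    })


def _healthy_field(params: SynthSectionParams, rng,
                   rules: CellClassRules) -> pd.DataFrame:
    """Healthy-tissue cells over the whole canvas.

    Serial sections cut 40 um apart traverse the same tissue, so this
    field is drawn once per stack and shared by every section — that
    continuity is what makes the sections registerable at all.  Per
    section, cells falling inside the lesion geometry are dropped.
    """
    w_um = params.width_px * params.um_per_px
    h_um = params.height_px * params.um_per_px
    area_mm2 = w_um * h_um * 1e-6
    everywhere = lambda p: np.ones(len(p), dtype=bool)  # noqa: E731
    blue = _field(rng, rng.poisson(params.outside_density * area_mm2),
                  w_um, h_um, everywhere, "blue", params, rules)
    brown = _field(rng, rng.poisson(params.outside_brown_density * area_mm2),
                   w_um, h_um, everywhere, "brown", params, rules)
    return pd.concat([blue, brown], ignore_index=True)


def _lesion_field(params: SynthSectionParams, rng, rules: CellClassRules,
                  R: float) -> pd.DataFrame:
    """Per-section lesion content: sparse interior blues, the dense brown
    boundary ring, and severity-dependent interior browns."""
    w_um = params.width_px * params.um_per_px
    h_um = params.height_px * params.um_per_px
    cx, cy = _lesion_center_um(params)
    R_out = R + params.ring_width_um

    def dist(p):
        return np.hypot(p[:, 0] - cx, p[:, 1] - cy)

    disk_mm2 = np.pi * R ** 2 * 1e-6
    ring_mm2 = np.pi * (R_out ** 2 - R ** 2) * 1e-6
    pieces = [_field(rng, rng.poisson(params.inside_density * disk_mm2),
                     w_um, h_um, lambda p: dist(p) <= R, "blue",
                     params, rules),
              _field(rng, rng.poisson(params.ring_brown_density * ring_mm2),
                     w_um, h_um,
                     lambda p: (dist(p) > R) & (dist(p) <= R_out), "brown",
                     params, rules)]
    if params.inside_brown_density > 0:
        pieces.append(_field(
            rng, rng.poisson(params.inside_brown_density * disk_mm2),
            w_um, h_um, lambda p: dist(p) <= R, "brown", params, rules))
    return pd.concat(pieces, ignore_index=True)


def _assemble_cells(params: SynthSectionParams, healthy: pd.DataFrame,
                    lesion: pd.DataFrame, R: float,
                    jitter: RigidTransform | None) -> pd.DataFrame:
    """Combine fields for one section, thin overlaps, apply rigid jitter."""
    cx, cy = _lesion_center_um(params)
    R_out = R + params.ring_width_um
    d = np.hypot(healthy["x_um"] - cx, healthy["y_um"] - cy)
    keep_healthy = np.where(healthy["cell_class"] == "blue",
                            d > R, d > R_out)
    cells = pd.concat([healthy[keep_healthy], lesion], ignore_index=True)

    # Coverage sanity check on the *requested* populations, before overlap
    # thinning silently caps the density.
    w_um = params.width_px * params.um_per_px
    h_um = params.height_px * params.um_per_px
    coverage = (np.pi * cells["radius_um"] ** 2).sum() / (w_um * h_um)
    if coverage > 0.8:
        raise InvalidParameterError(
            f"requested densities cover {coverage:.0%} of the slide; "
            "an actual section never exceeds ~80%")

    xy = cells[["x_um", "y_um"]].to_numpy()
    keep = _thin_overlaps(xy, min_sep_um=2.0 * params.cell_radius_um[0])
    cells = cells[keep].reset_index(drop=True)

    cells["area_um2"] = np.pi * cells["radius_um"] ** 2
    cells["centroid_col"] = cells["x_um"] / params.um_per_px
    cells["centroid_row"] = cells["y_um"] / params.um_per_px
    if jitter is not None:
        # Move the geometry itself (exact), not the rendered raster.
        M = jitter.matrix((params.height_px, params.width_px))
        pts = np.column_stack([cells["centroid_col"], cells["centroid_row"],
                               np.ones(len(cells))])
        moved = pts @ M.T
        cells["centroid_col"] = moved[:, 0]
        cells["centroid_row"] = moved[:, 1]
        inside = ((cells["centroid_col"] >= 0)
                  & (cells["centroid_col"] < params.width_px)
                  & (cells["centroid_row"] >= 0)
                  & (cells["centroid_row"] < params.height_px))
        cells = cells[inside].reset_index(drop=True)
    return cells


def _make_cell_table(params: SynthSectionParams, rng,
                     rules: CellClassRules,
                     jitter: RigidTransform | None = None) -> pd.DataFrame:
    healthy = _healthy_field(params, rng, rules)
    lesion = _lesion_field(params, rng, rules, params.region_radius_um)
    return _assemble_cells(params, healthy, lesion,
                           params.region_radius_um, jitter)


def gen_section(params: SynthSectionParams,
                rules: CellClassRules = CellClassRules(),
                _jitter: RigidTransform | None = None,
                depth_um: float = 0.0, section_id: str = "synth",
                ) -> tuple[SectionImage, NecrosisMap, pd.DataFrame]:
    """Render one synthetic section and its analytic ground truth.

    Returns ``(section, truth_map, truth_cells)``.  The truth map applies
    the same patch equations the pipeline uses to the *exact* generated
    cell geometry, so a pipeline run on the rendered raster can be scored
    against it.  Generation is bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    cells = _make_cell_table(params, rng, rules, jitter=_jitter)
    section, truth = _render_section(params, cells, depth_um, section_id)
    return section, truth, cells


def _render_section(params: SynthSectionParams, cells: pd.DataFrame,
                    depth_um: float, section_id: str
                    ) -> tuple[SectionImage, NecrosisMap]:
    canvas = np.empty((params.height_px, params.width_px, 3))
    canvas[:] = BACKGROUND_RGB
    _render_cells(canvas, cells, params.um_per_px)
    section = SectionImage(
        pixels=np.clip(np.round(canvas), 0, 255).astype(np.uint8),
        um_per_px=params.um_per_px, depth_um=depth_um,
        section_id=section_id)
    stats = patch_fractions(cells, params.width_px, params.height_px,
                            params.um_per_px, patch_um=params.patch_um)
    truth = necrosis_map(stats, depth_um=depth_um, section_id=section_id)
    return section, truth


@dataclass
class SynthStack:
    """A jittered serial-section stack plus its ground truth."""

    sections: list[SectionImage]
    truth_maps: list[NecrosisMap]          # in each section's own frame
    jitters: list[RigidTransform]          # base frame -> section frame
    radii_um: np.ndarray
    spacing_um: float
    lesion_volume_mm3: float               # analytic, interior disk only


def gen_stack(params: SynthSectionParams,
              n_sections: int = 5,
              spacing_um: float = 40.0,
              radius_growth_um_per_section: float = 0.0,
              max_jitter_deg: float = 0.0,
              max_jitter_px: float = 0.0,
              seed: int | None = None) -> SynthStack:
    """Generate a serial stack with optional growth and rigid jitter.

    The healthy-tissue cell field is drawn once and shared by all sections
    (consecutive 4-um sections traverse the same tissue, so its structure
    persists through the stack); the lesion content is redrawn per
    section.  The lesion radius grows linearly with depth (tissue
    curvature makes deeper sections larger); each section is rendered in
    its own jittered frame with the jitter recorded as ground truth.  The
    analytic lesion volume integrates pi r(z)^2 over depth.
    """
    if n_sections < 2:
        raise InvalidParameterError("n_sections must be >= 2")
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rules = CellClassRules()
    healthy = _healthy_field(params, rng, rules)
    sections, truths, jitters = [], [], []
    radii = params.region_radius_um \
        + radius_growth_um_per_section * np.arange(n_sections)
    for i in range(n_sections):
        if max_jitter_deg > 0 or max_jitter_px > 0:
            jit = RigidTransform(
                rotation_deg=rng.uniform(-max_jitter_deg, max_jitter_deg),
                translation=(rng.uniform(-max_jitter_px, max_jitter_px),
                             rng.uniform(-max_jitter_px, max_jitter_px)))
        else:
            jit = RigidTransform()
        sec_rng = np.random.default_rng(int(rng.integers(0, 2 ** 31 - 1)))
        lesion = _lesion_field(params, sec_rng, rules, float(radii[i]))
        cells = _assemble_cells(params, healthy, lesion, float(radii[i]),
                                jit)
        sec, truth = _render_section(params, cells, i * spacing_um,
                                     f"synth-{i:03d}")
        sections.append(sec)
        truths.append(truth)
        jitters.append(jit)
    # Analytic interior volume: trapezoid of pi r(z)^2 over the stack depth.
    z = np.arange(n_sections) * spacing_um
    vol_um3 = np.trapezoid(np.pi * radii ** 2, z)
    return SynthStack(sections=sections, truth_maps=truths, jitters=jitters,
                      radii_um=radii, spacing_um=spacing_um,
                      lesion_volume_mm3=float(vol_um3 * 1e-9))


@dataclass
class SynthTraceParams:
    """Piecewise-linear temperature trace breakpoints.

    Defaults follow the canonical three-phase heating curve of a strongly
    heated liver surface: fast linear rise to the enzyme-inactivation
    temperature, slower climb to the protein-denaturation threshold, then a
    plateau.
    """

    breakpoints: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 293.15), (0.34, 315.15),
                                 (3.88, 333.15), (20.0, 333.44)])
    step_s: float = 1.0

    def __post_init__(self) -> None:
        t = np.array([b[0] for b in self.breakpoints])
        T = np.array([b[1] for b in self.breakpoints])
        if not np.all(np.diff(t) > 0):
            raise InvalidParameterError("breakpoint times must increase")
        if np.any((T < 273.0) | (T > 400.0)):
            raise InvalidParameterError(
                "breakpoint temperatures must lie within 273-400 K")


def gen_temperature_trace(params: SynthTraceParams) -> TemperatureTrace:
    """Sample a piecewise-linear trace (breakpoint times in minutes)."""
    t_br = np.array([b[0] for b in params.breakpoints]) * 60.0  # s
    T_br = np.array([b[1] for b in params.breakpoints])
    times = np.arange(0.0, t_br[-1] + params.step_s / 2.0, params.step_s)
    T = np.interp(times, t_br, T_br)
    return TemperatureTrace(times=times, T=T)
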