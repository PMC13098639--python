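"""Quantitative necrosis mapping from digitized IHC sections.

A digitized cleaved Caspase-3 IHC section shows two cell populations:
DAB-positive apoptotic cells stained brown, and hematoxylin-stained
negative cells in blue.  Necrosis — the *absence* of caspase activation
inside the irradiated lesion — is scored per 200 um x 200 um patch as

    necrosis % = Gamma * exp(-k * rho) * 100,    k = 100

where Gamma is the blue fraction of the classified cell area,
``blue / (blue + brown)``, and rho is the brown cell area divided by the
patch area.  A patch full of blue cells and free of brown cells scores
100%; brown cells suppress the score steeply (the exponential produces the
sharp transition observed at the lesion boundary).

The module also covers the practical plumbing around that score: planning
the power-of-two mosaic decomposition used for whole-slide tiles under a
4 MB per-tile budget, splitting/stitching rasters losslessly, a pluggable
cell segmenter with a classical watershed default, RGB box classification
of cells, multilevel Otsu thresholding, and the two-stage artifact filter
that isolates the lesion component from spurious high-score background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation

from necrotherm.errors import (DegenerateHistogramError, DimensionError,
                               InvalidParameterError)

__all__ = [
    "SectionImage", "MosaicPlan", "CellSegmentation", "CellClassRules",
    "PatchStats", "NecrosisMap", "FilterResult", "plan_mosaic",
    "split_section", "stitch_section", "segment_cells", "classify_cells",
    "patch_fractions", "necrosis_from_patch", "necrosis_map",
    "multilevel_otsu", "stage1_centroid", "stage2_filter",
]

#: Default edge length of a scoring patch, um.
PATCH_UM = 200.0
#: Exponential decay constant of the necrosis score.
DECAY_K = 100.0


@dataclass
class SectionImage:
    """One digitized RGB section with physical metadata."""

    pixels: np.ndarray          # (H, W, 3) uint8
    um_per_px: float
    depth_um: float = 0.0
    section_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidParameterError("pixels must be an (H, W, 3) raster")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise InvalidParameterError("raster must be at least 1x1")
        if self.um_per_px <= 0:
            raise InvalidParameterError("um_per_px must be positive")

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


# ---------------------------------------------------------------------------
# Mosaic planning and lossless tiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MosaicPlan:
    """Power-of-two mosaic decomposition of a large section raster."""

    width: int
    height: int
    mosaic_cols: int
    mosaic_rows: int
    byte_bound: int = 4 * 1024 * 1024
    bytes_per_px: int = 4

    @property
    def tile_w(self) -> int:
        return -(-self.width // self.mosaic_cols)   # ceil division

    @property
    def tile_h(self) -> int:
        return -(-self.height // self.mosaic_rows)

    @property
    def n_tiles(self) -> int:
        return self.mosaic_cols * self.mosaic_rows


def plan_mosaic(width: int, height: int,
                byte_bound: int = 4 * 1024 * 1024) -> MosaicPlan:
    """Plan a power-of-two mosaic whose tiles fit a per-tile byte budget.

    Starting from a single tile, the mosaic count is doubled along the
    dimension whose current tile extent is larger (ties double columns)
    until ``tile_w * tile_h * 4`` bytes fits within ``byte_bound``.  With
    the default 4 MiB bound this reproduces the published whole-slide
    decompositions (e.g. a 103,680 x 101,376 px section into 16,384 tiles
    of 810 x 792 px).
    """
    if width < 1 or height < 1:
        raise InvalidParameterError("width and height must be >= 1")
    cols = rows = 1
    while -(-width // cols) * -(-height // rows) * 4 > byte_bound:
        if -(-width // cols) >= -(-height // rows):
            cols *= 2
        else:
            rows *= 2
    return MosaicPlan(width=width, height=height, mosaic_cols=cols,
                      mosaic_rows=rows, byte_bound=byte_bound)


def split_section(section: SectionImage | np.ndarray,
                  plan: MosaicPlan) -> list[np.ndarray]:
    """Cut the raster into row-major tiles; edge tiles may be smaller."""
    px = section.pixels if isinstance(section, SectionImage) else section
    h, w = px.shape[0], px.shape[1]
    if (w, h) != (plan.width, plan.height):
        raise DimensionError(
            f"plan is for {plan.width}x{plan.height}, raster is {w}x{h}")
    tw, th = plan.tile_w, plan.tile_h
    tiles = []
    for r in range(plan.mosaic_rows):
        for c in range(plan.mosaic_cols):
            tiles.append(px[r * th:(r + 1) * th, c * tw:(c + 1) * tw])
    return tiles


def stitch_section(tiles: Sequence[np.ndarray | None],
                   plan: MosaicPlan) -> np.ndarray:
    """Reassemble row-major tiles; the inverse of :func:`split_section`."""
    if len(tiles) != plan.n_tiles:
        raise DimensionError(
            f"expected {plan.n_tiles} tiles, got {len(tiles)}")
    rows = []
    for r in range(plan.mosaic_rows):
        row_tiles = []
        for c in range(plan.mosaic_cols):
            t = tiles[r * plan.mosaic_cols + c]
            if t is None:
                raise DimensionError(
                    f"missing tile at mosaic position (row {r}, col {c})")
            row_tiles.append(t)
        rows.append(np.concatenate(row_tiles, axis=1))
    out = np.concatenate(rows, axis=0)
    if out.shape[0] != plan.height or out.shape[1] != plan.width:
        raise DimensionError(
            f"stitched raster {out.shape[1]}x{out.shape[0]} does not match "
            f"plan {plan.width}x{plan.height}")
    return out


# ---------------------------------------------------------------------------
# Cell segmentation (pluggable) and classification
# ---------------------------------------------------------------------------

@dataclass
class CellSegmentation:
    """Label raster plus a per-cell statistics table.

    ``cells`` columns: label, area_um2, r_mean, g_mean, b_mean,
    centroid_row, centroid_col (pixels).
    """

    labels: np.ndarray
    cells: pd.DataFrame
    um_per_px: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _default_segmenter(tile: np.ndarray, um_per_px: float,
                       min_diameter_um: float = 3.0,
                       max_diameter_um: float = 20.0) -> np.ndarray:
    """Classical stain-agnostic cell segmentation.

    Foreground (stained cells are darker than the near-white background) is
    separated with Otsu's threshold on the mean channel, holes are filled,
    touching cells are split by a distance-transform watershed and objects
    outside a plausible cell-area band are dropped.
    """
    gray = tile.astype(float).mean(axis=2)
    if gray.max() - gray.min() < 20.0:   # blank tile: no stained objects
        return np.zeros(gray.shape, dtype=np.int32)
    th = filters.threshold_otsu(gray)
    fg = gray < th
    fg = ndi.binary_fill_holes(fg)
    min_area_px = np.pi * (min_diameter_um / 2.0 / um_per_px) ** 2
    max_area_px = np.pi * (max_diameter_um / 2.0 / um_per_px) ** 2
    fg = morphology.remove_small_objects(
        fg, max_size=max(1, int(min_area_px * 0.5)))
    if not fg.any():
        return np.zeros(gray.shape, dtype=np.int32)
    # Watershed on the distance transform to split touching cells.
    dist = ndi.distance_transform_edt(fg)
    min_sep = max(2, int(round(min_diameter_um / um_per_px * 0.7)))
    from skimage.feature import peak_local_max
    peaks = peak_local_max(dist, min_distance=min_sep, labels=fg,
                           exclude_border=False)
    markers = np.zeros(gray.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-dist, markers, mask=fg)
    # Drop objects outside the plausible area band, then relabel 1..N.
    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < min_area_px) | (areas > max_area_px))
    labels[np.isin(labels, bad[bad > 0])] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_cells(tile: np.ndarray, um_per_px: float,
                  segmenter: Callable[..., np.ndarray] | None = None
                  ) -> CellSegmentation:
    """Segment cells in an RGB tile and tabulate per-cell statistics.

    ``segmenter`` maps ``(tile, um_per_px) -> label raster`` (0 =
    background, 1..N = cells); any callable honouring that contract can
    replace the classical default (e.g. a neural segmenter).
    """
    tile = np.asarray(tile)
    if tile.size == 0:
        raise InvalidParameterError("tile must be non-empty")
    if segmenter is None:
        segmenter = _default_segmenter
    labels = segmenter(tile, um_per_px)
    props = measure.regionprops(labels, intensity_image=tile.astype(float))
    rows = []
    for p in props:
        mean_rgb = p.intensity_mean  # (3,) vector for multichannel input
        rows.append((p.label, p.area * um_per_px ** 2, mean_rgb[0],
                     mean_rgb[1], mean_rgb[2], p.centroid[0], p.centroid[1]))
    cells = pd.DataFrame(rows, columns=["label", "area_um2", "r_mean",
                                        "g_mean", "b_mean", "centroid_row",
                                        "centroid_col"])
    return CellSegmentation(labels=labels, cells=cells, um_per_px=um_per_px)


@dataclass(frozen=True)
class CellClassRules:
    """RGB box thresholds for DAB-brown and hematoxylin-blue cells.

    Defaults are the empirical boxes: brown if 60 <= R <= 210, G <= 151,
    B <= 130; blue if 150 <= R <= 186, G >= 155, B >= 160.  The G ranges
    make the boxes disjoint.
    """

    brown_r: tuple[float, float] = (60.0, 210.0)
    brown_g_max: float = 151.0
    brown_b_max: float = 130.0
    blue_r: tuple[float, float] = (150.0, 186.0)
    blue_g_min: float = 155.0
    blue_b_min: float = 160.0

    def __post_init__(self) -> None:
        if self.brown_g_max >= self.blue_g_min:
            raise InvalidParameterError(
                "brown and blue G ranges overlap; boxes must be disjoint")

    def is_brown(self, r, g, b):
        return ((self.brown_r[0] <= r) & (r <= self.brown_r[1])
                & (g <= self.brown_g_max) & (b <= self.brown_b_max))

    def is_blue(self, r, g, b):
        return ((self.blue_r[0] <= r) & (r <= self.blue_r[1])
                & (g >= self.blue_g_min) & (b >= self.blue_b_min))


def classify_cells(seg: CellSegmentation,
                   rules: CellClassRules = CellClassRules()) -> pd.DataFrame:
    """Assign each segmented cell to {brown, blue, unclassified}.

    Classification applies the RGB boxes to the cell's *mean* RGB; cells
    matching neither box are unclassified and excluded from all area
    statistics downstream.
    """
    cells = seg.cells.copy()
    if len(cells) == 0:
        cells["cell_class"] = pd.Series(dtype=object)
        return cells
    r = cells["r_mean"].to_numpy()
    g = cells["g_mean"].to_numpy()
    b = cells["b_mean"].to_numpy()
    cls = np.full(len(cells), "unclassified", dtype=object)
    cls[rules.is_blue(r, g, b)] = "blue"
    cls[rules.is_brown(r, g, b)] = "brown"  # brown box checked first wins
    cells["cell_class"] = cls
    return cells


# ---------------------------------------------------------------------------
# Patch statistics and the necrosis score
# ---------------------------------------------------------------------------

@dataclass
class PatchStats:
    """Per-patch blue/brown areas and the Gamma / rho statistics.

    ``gamma`` is NaN where no classified cell area falls in the patch
    (undefined 0/0); ``defined`` flags those patches.
    """

    blue_area: np.ndarray     # um^2, shape (rows, cols)
    brown_area: np.ndarray    # um^2
    patch_area: np.ndarray    # um^2 (edge patches truncated)
    patch_um: float = PATCH_UM
    decay_k: float = DECAY_K

    @property
    def gamma(self) -> np.ndarray:
        tot = self.blue_area + self.brown_area
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.blue_area / tot, np.nan)

    @property
    def rho_brown(self) -> np.ndarray:
        return self.brown_area / self.patch_area

    @property
    def defined(self) -> np.ndarray:
        return (self.blue_area + self.brown_area) > 0


def patch_fractions(classified: pd.DataFrame,
                    width_px: int, height_px: int, um_per_px: float,
                    patch_um: float = PATCH_UM,
                    decay_k: float = DECAY_K) -> PatchStats:
    """Accumulate classified cell areas onto the 200-um patch grid.

    Patches are non-overlapping squares anchored at the raster origin; a
    cell contributes its whole area to the patch containing its centroid.
    Edge patches are truncated and use their true area as the denominator
    of rho.
    """
    if um_per_px <= 0:
        raise InvalidParameterError("um_per_px metadata is required")
    patch_px = patch_um / um_per_px
    n_cols = max(1, int(np.ceil(width_px / patch_px)))
    n_rows = max(1, int(np.ceil(height_px / patch_px)))
    blue = np.zeros((n_rows, n_cols))
    brown = np.zeros((n_rows, n_cols))
    if len(classified):
        pr = np.minimum((classified["centroid_row"].to_numpy()
                         / patch_px).astype(int), n_rows - 1)
        pc = np.minimum((classified["centroid_col"].to_numpy()
                         / patch_px).astype(int), n_cols - 1)
        area = classified["area_um2"].to_numpy()
        cls = classified["cell_class"].to_numpy()
        for arr, name in ((blue, "blue"), (brown, "brown")):
            sel = cls == name
            np.add.at(arr, (pr[sel], pc[sel]), area[sel])
    # True (possibly truncated) physical patch areas.
    col_w = np.full(n_cols, patch_um)
    col_w[-1] = width_px * um_per_px - (n_cols - 1) * patch_um
    row_h = np.full(n_rows, patch_um)
    row_h[-1] = height_px * um_per_px - (n_rows - 1) * patch_um
    patch_area = np.outer(row_h, col_w)
    return PatchStats(blue_area=blue, brown_area=brown,
                      patch_area=patch_area, patch_um=patch_um,
                      decay_k=decay_k)


def necrosis_from_patch(gamma, rho_brown, decay_k: float = DECAY_K):
    """Patch necrosis percentage: Gamma * exp(-k rho) * 100.

    Undefined Gamma (NaN: a patch with no classified cells) scores 0%.
    """
    gamma = np.asarray(gamma, dtype=float)
    rho = np.asarray(rho_brown, dtype=float)
    out = np.where(np.isnan(gamma), 0.0,
                   np.nan_to_num(gamma) * np.exp(-decay_k * rho) * 100.0)
    return out if out.ndim else float(out)


@dataclass
class NecrosisMap:
    """Patch-grid of necrosis percentages for one section."""

    values: np.ndarray        # (rows, cols), each in [0, 100]
    patch_um: float = PATCH_UM
    depth_um: float = 0.0
    section_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("necrosis map must be 2-D")
        if np.nanmin(self.values) < -1e-9 or np.nanmax(self.values) > 100 + 1e-9:
            raise InvalidParameterError("necrosis values must lie in [0, 100]")


def necrosis_map(stats: PatchStats, depth_um: float = 0.0,
                 section_id: str = "") -> NecrosisMap:
    """Evaluate the necrosis score on a patch-statistics grid."""
    vals = necrosis_from_patch(stats.gamma, stats.rho_brown, stats.decay_k)
    return NecrosisMap(values=vals, patch_um=stats.patch_um,
                       depth_um=depth_um, section_id=section_id)


# ---------------------------------------------------------------------------
# Multilevel Otsu and the two-stage artifact filter
# ---------------------------------------------------------------------------

def multilevel_otsu(values: np.ndarray, n_thresholds: int = 3,
                    nbins: int = 256) -> np.ndarray:
    """Otsu thresholds maximizing between-class variance.

    Values are binned into an ``nbins``-bin histogram after affine scaling
    to [0, nbins - 1]; the returned thresholds are mapped back to the input
    scale.  Deterministic; raises :class:`DegenerateHistogramError` when
    the input has fewer than ``n_thresholds + 1`` distinct values.
    """
    values = np.asarray(values, dtype=float).ravel()
    uniq = np.unique(values)
    if uniq.size < n_thresholds + 1:
        raise DegenerateHistogramError(
            f"need at least {n_thresholds + 1} distinct values, "
            f"got {uniq.size}")
    lo, hi = float(uniq[0]), float(uniq[-1])
    scaled = (values - lo) / (hi - lo) * (nbins - 1.0)
    th = filters.threshold_multiotsu(scaled, classes=n_thresholds + 1,
                                     nbins=nbins)
    return th / (nbins - 1.0) * (hi - lo) + lo


def _binarize(values: np.ndarray, n_thresholds: int = 3) -> np.ndarray:
    """Binary lesion candidate mask: above the second Otsu threshold."""
    th = multilevel_otsu(values, n_thresholds)
    return values >= th[1]


@dataclass
class FilterResult:
    """Outcome of the stage-2 artifact filter for one necrosis map."""

    stage1_centroid: tuple[float, float]
    kept_label: int | None
    filtered: NecrosisMap
    warning: bool = False


def stage1_centroid(maps: Sequence[NecrosisMap | np.ndarray]
                    ) -> tuple[float, float]:
    """Locate the lesion centroid on the average of registered maps.

    The registered maps are averaged, thresholded at the second of three
    Otsu thresholds, and the connected component containing the global
    maximum of the average map is kept; its centroid (row, col in patch
    units) anchors the per-section filtering of :func:`stage2_filter`.
    """
    if len(maps) < 2:
        raise InvalidParameterError("need at least 2 registered maps")
    arrays = [m.values if isinstance(m, NecrosisMap) else np.asarray(m)
              for m in maps]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise DimensionError("all maps must share a common grid")
    avg = np.mean(arrays, axis=0)
    binary = _binarize(avg)      # raises DegenerateHistogramError if flat
    if not binary.any():
        raise InvalidParameterError("empty binary image after thresholding")
    labels = measure.label(binary)
    max_pos = np.unravel_index(np.argmax(avg), avg.shape)
    keep = labels[max_pos]
    if keep == 0:  # the maximum fell on background; take nearest component
        nz = np.argwhere(labels > 0)
        d2 = ((nz - np.asarray(max_pos)) ** 2).sum(axis=1)
        keep = labels[tuple(nz[np.argmin(d2)])]
    centroid = measure.regionprops((labels == keep).astype(int))[0].centroid
    return float(centroid[0]), float(centroid[1])


def stage2_filter(nmap: NecrosisMap, centroid: tuple[float, float],
                  solidity_min: float = 0.6) -> FilterResult:
    """Keep only the lesion component of one necrosis map.

    The map is binarized with the same second-of-three Otsu rule,
    components with solidity below ``solidity_min`` are discarded as
    artifacts, and among the survivors the component whose centroid is
    nearest the stage-1 centroid masks the map.  When nothing survives the
    result is an all-zero map flagged with ``warning=True``.
    """
    zero = NecrosisMap(values=np.zeros_like(nmap.values),
                       patch_um=nmap.patch_um, depth_um=nmap.depth_um,
                       section_id=nmap.section_id)
    try:
        binary = _binarize(nmap.values)
    except DegenerateHistogramError:
        return FilterResult(stage1_centroid=centroid, kept_label=None,
                            filtered=zero, warning=True)
    labels = measure.label(binary)
    best_label, best_d2 = None, np.inf
    for p in measure.regionprops(labels):
        if p.solidity < solidity_min:
            continue
        d2 = (p.centroid[0] - centroid[0]) ** 2 \
            + (p.centroid[1] - centroid[1]) ** 2
        if d2 < best_d2:
            best_label, best_d2 = p.label, d2
    if best_label is None:
        return FilterResult(stage1_centroid=centroid, kept_label=None,
                            filtered=zero, warning=True)
    mask = labels == best_label
    filtered = NecrosisMap(values=nmap.values * mask,
                           patch_um=nmap.patch_um, depth_um=nmap.depth_um,
                           section_id=nmap.section_id)
    return FilterResult(stage1_centroid=centroid, kept_label=int(best_label),
                        filtered=filtered, warning=False)


# ---------------------------------------------------------------------------
# Section-level convenience driver
# ---------------------------------------------------------------------------

def quantify_section(section: SectionImage,
                     rules: CellClassRules = CellClassRules(),
                     segmenter: Callable[..., np.ndarray] | None = None,
                     patch_um: float = PATCH_UM,
                     plan: MosaicPlan | None = None
                     ) -> tuple[NecrosisMap, pd.DataFrame]:
    """Segment, classify and score a whole section.

    Large sections are processed tile-by-tile following ``plan`` (planned
    automatically when None); cell centroids are shifted back into
    section coordinates before patch accumulation.  Returns the necrosis
    map and the full classified-cell table.
    """
    h, w = section.shape_px
    if plan is None:
        plan = plan_mosaic(w, h)
    tiles = split_section(section, plan)
    tw, th = plan.tile_w, plan.tile_h
    tables = []
    for i, tile in enumerate(tiles):
        if tile.size == 0:
            continue
        r, c = divmod(i, plan.mosaic_cols)
        seg = segment_cells(tile, section.um_per_px, segmenter)
        cls = classify_cells(seg, rules)
        if len(cls) == 0:
            continue
        cls = cls.copy()
        cls["centroid_row"] += r * th
        cls["centroid_col"] += c * tw
        tables.append(cls)
    if tables:
        cells = pd.concat(tables, ignore_index=True)
    else:
        cells = pd.DataFrame(columns=["label", "area_um2", "r_mean",
                                      "g_mean", "b_mean", "centroid_row",
                                      "centroid_col", "cell_class"])
    stats = patch_fractions(cells, w, h, section.um_per_px,
                            patch_um=patch_um)
    nmap = necrosis_map(stats, depth_um=section.depth_um,
                        section_id=section.section_id)
    return nmap, cells
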