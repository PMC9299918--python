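"""Tile-based spatial quantification of immune-cell densities.

The sample is divided into a grid of square tiles (default area 2 mm^2, side
sqrt(2) mm) anchored at the tissue bounding box.  Tumor-containing tiles
(non-zero pan-cytokeratin+ area) are classed tumor-center (TC) or
invasive-margin (IM) by proximity to the tumor-region boundary; tiles without
epithelium are non-tumor stroma.  Cells are assigned to three compartments —
tumor epithelium, tumor stroma (non-epithelial tissue inside tumor tiles) and
non-tumor stroma — and mean densities (cells/mm^2 of compartment tissue) are
averaged over tiles, the tile being the unit of observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import IMMUNE_MARKERS, TissueSample

COMPARTMENTS = ("tumor_epithelium", "tumor_stroma", "non_tumor_stroma")
REGIONS = ("TC", "IM", "all")


@dataclass
class TileGrid:
    """Square-tile partition of a sample's tissue bounding box.

    ``tiles`` has one row per retained tile: ``ix, iy, x0_um, y0_um,
    tissue_area_mm2, epithelium_area_mm2, tile_class``.
    """

    origin_um: tuple[float, float]
    side_um: float
    nx: int
    ny: int
    um_per_px: float
    tiles: pd.DataFrame
    params: dict

    @property
    def tile_area_mm2(self) -> float:
        return (self.side_um / 1000.0) ** 2

    def tile_bin(self, x_um: np.ndarray, y_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ix = np.floor((np.asarray(x_um) - self.origin_um[0]) / self.side_um).astype(int)
        iy = np.floor((np.asarray(y_um) - self.origin_um[1]) / self.side_um).astype(int)
        return ix, iy


def _pixel_tile_bins(
    mask_shape: tuple[int, int], grid_origin_px: tuple[int, int], side_px: float, um_per_px: float
):
    """Per-pixel (ix, iy) tile indices for a full raster (vectorized)."""
    ny, nx = mask_shape
    r0, c0 = grid_origin_px
    cols = np.arange(nx)
    rows = np.arange(ny)
    ix = np.floor((cols - c0 + 0.5) / side_px).astype(int)
    iy = np.floor((rows - r0 + 0.5) / side_px).astype(int)
    return ix, iy


def build_tile_grid(
    sample: TissueSample,
    tile_area_mm2: float = 2.0,
    min_tissue_fraction: float = 0.1,
) -> TileGrid:
    """Tile the tissue bounding box with squares of area ``tile_area_mm2``.

    Every tissue pixel belongs to exactly one tile; tiles whose tissue area is
    below ``min_tissue_fraction`` of the tile's geometric area are dropped to
    avoid unstable density denominators.
    """
    if tile_area_mm2 <= 0:
        raise ValueError("tile_area must be positive")
    tissue = sample.tissue_mask
    if not tissue.any():
        raise ValueError("empty tissue mask")
    px = sample.um_per_px
    px_area_mm2 = (px / 1000.0) ** 2
    side_um = math.sqrt(tile_area_mm2) * 1000.0
    side_px = side_um / px

    rows_any = np.nonzero(tissue.any(axis=1))[0]
    cols_any = np.nonzero(tissue.any(axis=0))[0]
    r0, r1 = int(rows_any[0]), int(rows_any[-1])
    c0, c1 = int(cols_any[0]), int(cols_any[-1])
    extent_x = (c1 - c0 + 1) * px
    extent_y = (r1 - r0 + 1) * px
    nx = max(1, int(math.ceil(extent_x / side_um - 1e-9)))
    ny = max(1, int(math.ceil(extent_y / side_um - 1e-9)))

    ix_of_col, iy_of_row = _pixel_tile_bins(tissue.shape, (r0, c0), side_px, px)
    ix_of_col = np.clip(ix_of_col, 0, nx - 1)
    iy_of_row = np.clip(iy_of_row, 0, ny - 1)

    flat = iy_of_row[:, None] * nx + ix_of_col[None, :]
    tissue_counts = np.bincount(flat[tissue], minlength=nx * ny)
    epi_counts = np.bincount(flat[sample.epithelium_mask], minlength=nx * ny)

    records = []
    min_area = min_tissue_fraction * tile_area_mm2
    if not any(
        tissue_counts[i] * px_area_mm2 >= min_area and tissue_counts[i] > 0
        for i in range(nx * ny)
    ):
        min_area = 0.0  # never drop every tile (e.g. a small biopsy fragment)
    for iy in range(ny):
        for ix in range(nx):
            t_area = tissue_counts[iy * nx + ix] * px_area_mm2
            if t_area < min_area or t_area == 0:
                continue
            records.append(
                {
                    "ix": ix,
                    "iy": iy,
                    "x0_um": c0 * px + ix * side_um,
                    "y0_um": r0 * px + iy * side_um,
                    "tissue_area_mm2": t_area,
                    "epithelium_area_mm2": epi_counts[iy * nx + ix] * px_area_mm2,
                    "tile_class": "unclassified",
                }
            )
    tiles = pd.DataFrame(
        records,
        columns=[
            "ix", "iy", "x0_um", "y0_um",
            "tissue_area_mm2", "epithelium_area_mm2", "tile_class",
        ],
    )
    return TileGrid(
        origin_um=(c0 * px, r0 * px),
        side_um=side_um,
        nx=nx,
        ny=ny,
        um_per_px=px,
        tiles=tiles,
        params={
            "tile_area_mm2": tile_area_mm2,
            "min_tissue_fraction": min_tissue_fraction,
            "bbox_px": (r0, r1, c0, c1),
        },
    )


def classify_tiles(
    grid: TileGrid,
    epithelium_mask: np.ndarray,
    im_band_um: float = 500.0,
    closing_radius_um: float = 800.0,
) -> TileGrid:
    """Assign TC / IM / non_tumor classes to tiles.

    The tumor region is the morphological closing of the epithelium mask
    (disk of ``closing_radius_um``); tumor-containing tiles intersecting the
    inner band within ``im_band_um`` of the region boundary (the slide edge
    counts as boundary) are IM, the remaining tumor-containing tiles TC, and
    epithelium-free tiles non_tumor.
    """
    px = grid.um_per_px
    epi = np.asarray(epithelium_mask, dtype=bool)

    if epi.any():
        # disc closing via two distance transforms (fast for large radii):
        # dilation = {dist to foreground <= r}, then erosion of that set
        rpx = max(1, int(round(closing_radius_um / px)))
        pad = rpx + 1
        padded = np.pad(epi, pad)
        dilated = ndimage.distance_transform_edt(~padded) <= rpx
        region = ndimage.distance_transform_edt(dilated) > rpx
        # interior stroma enclosed by epithelium is tumor region too
        region = ndimage.binary_fill_holes(region)[pad:-pad, pad:-pad]
        # distance to the region boundary; outside the image counts as outside
        dist = ndimage.distance_transform_edt(np.pad(region, 1))[1:-1, 1:-1] * px
        band = region & (dist <= im_band_um)
    else:
        band = np.zeros_like(epi)

    r0, _, c0, _ = grid.params["bbox_px"]
    side_px = grid.side_um / px
    ix_of_col, iy_of_row = _pixel_tile_bins(epi.shape, (r0, c0), side_px, px)
    ix_of_col = np.clip(ix_of_col, 0, grid.nx - 1)
    iy_of_row = np.clip(iy_of_row, 0, grid.ny - 1)
    flat = iy_of_row[:, None] * grid.nx + ix_of_col[None, :]
    band_counts = np.bincount(flat[band], minlength=grid.nx * grid.ny)

    tiles = grid.tiles.copy()
    classes = []
    for _, t in tiles.iterrows():
        if t["epithelium_area_mm2"] <= 0:
            classes.append("non_tumor")
        elif band_counts[int(t["iy"]) * grid.nx + int(t["ix"])] > 0:
            classes.append("IM")
        else:
            classes.append("TC")
    tiles["tile_class"] = classes
    params = dict(grid.params)
    params.update({"im_band_um": im_band_um, "closing_radius_um": closing_radius_um})
    return dc_replace(grid, tiles=tiles, params=params)


def assign_compartments(
    cells: pd.DataFrame,
    epithelium_mask: np.ndarray,
    grid: TileGrid,
) -> tuple[pd.DataFrame, int]:
    """Label each cell with its tile and compartment.

    Epithelium-pixel cells are ``tumor_epithelium``; other cells in
    tumor-containing tiles are ``tumor_stroma``; cells in non-tumor tiles are
    ``non_tumor_stroma``.  Cells outside every retained tile are dropped and
    counted.  Multipositive cells keep their labels but carry the
    ``multipositive`` exclusion flag.
    """
    px = grid.um_per_px
    epi = np.asarray(epithelium_mask, dtype=bool)
    ny, nx = epi.shape
    out = cells.copy().reset_index(drop=True)
    if len(out) == 0:
        out["tile_ix"] = pd.Series(dtype=int)
        out["tile_iy"] = pd.Series(dtype=int)
        out["tile_class"] = pd.Series(dtype=object)
        out["compartment"] = pd.Series(dtype=object)
        return out, 0

    ix, iy = grid.tile_bin(out["x_um"].to_numpy(), out["y_um"].to_numpy())
    key = pd.MultiIndex.from_arrays([ix, iy])
    tile_lookup = grid.tiles.set_index(["ix", "iy"])
    known = tile_lookup.index
    in_grid = key.isin(known)
    n_dropped = int((~in_grid).sum())
    out = out.loc[in_grid].reset_index(drop=True)
    ix, iy = ix[in_grid], iy[in_grid]

    cls = tile_lookup.loc[list(zip(ix, iy)), "tile_class"].to_numpy()
    col = np.clip((out["x_um"].to_numpy() / px).astype(int), 0, nx - 1)
    row = np.clip((out["y_um"].to_numpy() / px).astype(int), 0, ny - 1)
    on_epi = epi[row, col]

    compartment = np.where(
        on_epi,
        "tumor_epithelium",
        np.where(cls == "non_tumor", "non_tumor_stroma", "tumor_stroma"),
    )
    out["tile_ix"] = ix
    out["tile_iy"] = iy
    out["tile_class"] = cls
    out["compartment"] = compartment
    return out, n_dropped


@dataclass
class CompartmentDensities:
    """Mean densities per marker x compartment x region, plus combined metrics.

    ``table`` is tidy (marker, compartment, region, density_cells_per_mm2);
    ``tc_combined`` / ``im_combined`` are the mean per-tile combined TAIC
    densities (cells per mm^2 of tile tissue) over TC / IM tiles — the inputs
    of the landscape classifier.  ``tc_im_ratio`` is flagged undefined (nan)
    when the IM density is zero.
    """

    table: pd.DataFrame
    combined: dict
    tc_combined: float
    im_combined: float
    tc_im_ratio: float
    ratio_defined: bool
    n_tiles: dict
    per_tile: pd.DataFrame
    tile_average: bool = True


def _compartment_areas(tiles: pd.DataFrame) -> pd.DataFrame:
    """Per-tile areas (mm^2) of the three compartments."""
    tumor = tiles["tile_class"].isin(["TC", "IM"])
    areas = pd.DataFrame(
        {
            "ix": tiles["ix"],
            "iy": tiles["iy"],
            "tile_class": tiles["tile_class"],
            "tissue_area_mm2": tiles["tissue_area_mm2"],
            "tumor_epithelium": np.where(tumor, tiles["epithelium_area_mm2"], 0.0),
            "tumor_stroma": np.where(
                tumor, tiles["tissue_area_mm2"] - tiles["epithelium_area_mm2"], 0.0
            ),
            "non_tumor_stroma": np.where(~tumor, tiles["tissue_area_mm2"], 0.0),
        }
    )
    return areas


def compute_densities(
    cells: pd.DataFrame,
    grid: TileGrid,
    tile_average: bool = True,
    markers: tuple[str, ...] = IMMUNE_MARKERS,
) -> CompartmentDensities:
    """Mean immune-cell densities by marker, compartment and region.

    Multipositive cells are excluded.  Per tile and compartment the density is
    count / compartment area; the reported mean is the unweighted mean over
    tiles with non-zero compartment area (``tile_average=False`` switches to
    pooled counts / pooled area).  ``combined`` sums the three markers' means;
    the TC/IM ratio divides the combined per-tile TAIC tissue densities.
    """
    if len(grid.tiles) == 0:
        raise ValueError("grid has no tiles")
    areas = _compartment_areas(grid.tiles)
    use = cells[
        (~cells["multipositive"]) & cells["phenotype"].isin(markers)
    ] if len(cells) else cells

    counts = (
        use.groupby(["tile_ix", "tile_iy", "phenotype", "compartment"])
        .size()
        .rename("n")
        .reset_index()
        if len(use)
        else pd.DataFrame(columns=["tile_ix", "tile_iy", "phenotype", "compartment", "n"])
    )

    region_of = {"TC": "TC", "IM": "IM", "non_tumor": "non_tumor"}
    rows = []
    per_tile_rows = []
    for _, tile in areas.iterrows():
        ix, iy = int(tile["ix"]), int(tile["iy"])
        sub = counts[(counts["tile_ix"] == ix) & (counts["tile_iy"] == iy)]
        taic_n = int(sub["n"].sum())
        rec = {
            "ix": ix,
            "iy": iy,
            "tile_class": tile["tile_class"],
            "tissue_area_mm2": tile["tissue_area_mm2"],
            "taic_per_mm2": taic_n / tile["tissue_area_mm2"],
        }
        for m in markers:
            rec[f"{m}_per_mm2"] = (
                int(sub[sub["phenotype"] == m]["n"].sum()) / tile["tissue_area_mm2"]
            )
            for comp in COMPARTMENTS:
                area = float(tile[comp])
                n = int(
                    sub[(sub["phenotype"] == m) & (sub["compartment"] == comp)]["n"].sum()
                )
                rows.append(
                    {
                        "ix": ix,
                        "iy": iy,
                        "tile_class": tile["tile_class"],
                        "marker": m,
                        "compartment": comp,
                        "area_mm2": area,
                        "n": n,
                    }
                )
        per_tile_rows.append(rec)
    tile_table = pd.DataFrame(rows)
    per_tile = pd.DataFrame(per_tile_rows)

    def _mean_density(sub: pd.DataFrame) -> float:
        sub = sub[sub["area_mm2"] > 0]
        if len(sub) == 0:
            return math.nan
        if tile_average:
            return float((sub["n"] / sub["area_mm2"]).mean())
        return float(sub["n"].sum() / sub["area_mm2"].sum())

    out_rows = []
    for m in markers:
        for comp in COMPARTMENTS:
            base = tile_table[
                (tile_table["marker"] == m) & (tile_table["compartment"] == comp)
            ]
            for region in REGIONS:
                sub = base if region == "all" else base[base["tile_class"] == region]
                out_rows.append(
                    {
                        "marker": m,
                        "compartment": comp,
                        "region": region,
                        "density_cells_per_mm2": _mean_density(sub),
                    }
                )
    table = pd.DataFrame(out_rows)

    combined = {}
    for comp in COMPARTMENTS:
        for region in REGIONS:
            vals = table[
                (table["compartment"] == comp) & (table["region"] == region)
            ]["density_cells_per_mm2"]
            combined[(comp, region)] = float(vals.sum()) if vals.notna().any() else math.nan

    def _region_taic(region: str) -> float:
        sub = per_tile[per_tile["tile_class"] == region]
        if len(sub) == 0:
            return 0.0
        if tile_average:
            return float(sub["taic_per_mm2"].mean())
        return float(
            (sub["taic_per_mm2"] * sub["tissue_area_mm2"]).sum()
            / sub["tissue_area_mm2"].sum()
        )

    tc = _region_taic("TC")
    im = _region_taic("IM")
    ratio_defined = im > 0
    ratio = tc / im if ratio_defined else math.nan
    n_tiles = grid.tiles["tile_class"].value_counts().to_dict()

    return CompartmentDensities(
        table=table,
        combined=combined,
        tc_combined=tc,
        im_combined=im,
        tc_im_ratio=ratio,
        ratio_defined=ratio_defined,
        n_tiles=n_tiles,
        per_tile=per_tile,
        tile_average=tile_average,
    )


def density_heatmap(
    grid: TileGrid, densities: CompartmentDensities, marker: str
) -> np.ndarray:
    """ny x nx matrix of per-tile tissue densities; missing tiles are NaN."""
    col = "taic_per_mm2" if marker in ("TAIC", "combined") else f"{marker}_per_mm2"
    if col not in densities.per_tile.columns:
        raise ValueError(f"unknown marker {marker!r}")
    mat = np.full((grid.ny, grid.nx), np.nan)
    for _, t in densities.per_tile.iterrows():
        mat[int(t["iy"]), int(t["ix"])] = t[col]
    return mat


def paired_delta(
    biopsy: CompartmentDensities, resection: CompartmentDensities
) -> pd.DataFrame:
    """Per-marker, per-compartment, per-region density deltas (resection - biopsy).

    Entries missing in either sample (no contributing tiles) are NaN.
    """
    b = biopsy.table.set_index(["marker", "compartment", "region"])
    r = resection.table.set_index(["marker", "compartment", "region"])
    out = (
        (r["density_cells_per_mm2"] - b["density_cells_per_mm2"])
        .rename("delta_cells_per_mm2")
        .reset_index()
    )
    return out
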