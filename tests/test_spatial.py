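"""Tile grid geometry, TC/IM classification, compartment assignment and
density computation against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from immunoscape import (
    assign_compartments,
    build_tile_grid,
    classify_tiles,
    compute_densities,
    density_heatmap,
    paired_delta,
)

from conftest import cell_frame, make_sample


class TestBuildTileGrid:
    def test_nine_tiles_for_three_by_three_block(self):
        # 4.243 x 4.243 mm of tissue = 3 x 3 tiles of side sqrt(2) mm; the
        # sub-micrometre sliver beyond the third tile has ~0 tissue and drops
        s = make_sample(cell_frame([], [], []), shape=(1415, 1415), um_per_px=3.0)
        grid = build_tile_grid(s, tile_area_mm2=2.0)
        assert len(grid.tiles) == 9
        assert grid.side_um == pytest.approx(np.sqrt(2.0) * 1000.0)

    def test_tissue_smaller_than_tile(self):
        s = make_sample(cell_frame([], [], []), shape=(50, 50), um_per_px=8.0)
        grid = build_tile_grid(s, tile_area_mm2=2.0)
        assert len(grid.tiles) == 1
        assert grid.tiles["tissue_area_mm2"].iloc[0] == pytest.approx(0.16)

    def test_tile_areas_sum_to_mask_area(self, rng):
        tissue = rng.random((300, 300)) < 0.6
        s = make_sample(cell_frame([], [], []), shape=(300, 300), um_per_px=8.0,
                        tissue=tissue)
        grid = build_tile_grid(s, tile_area_mm2=2.0, min_tissue_fraction=0.0)
        px_area = (8.0 / 1000.0) ** 2
        assert grid.tiles["tissue_area_mm2"].sum() == pytest.approx(
            tissue.sum() * px_area, abs=px_area
        )

    def test_empty_tissue_raises(self):
        s = make_sample(cell_frame([], [], []), tissue=np.zeros((50, 50), bool))
        with pytest.raises(ValueError, match="empty tissue"):
            build_tile_grid(s)

    def test_epithelium_within_tissue_per_tile(self, rng):
        tissue = np.ones((300, 300), bool)
        epi = rng.random((300, 300)) < 0.3
        s = make_sample(cell_frame([], [], []), shape=(300, 300), um_per_px=8.0,
                        epithelium=epi, tissue=tissue)
        grid = build_tile_grid(s)
        assert (grid.tiles["epithelium_area_mm2"]
                <= grid.tiles["tissue_area_mm2"] + 1e-12).all()


class TestClassifyTiles:
    def test_no_epithelium_all_non_tumor(self):
        s = make_sample(cell_frame([], [], []), shape=(400, 400), um_per_px=8.0)
        grid = classify_tiles(build_tile_grid(s), s.epithelium_mask)
        assert set(grid.tiles["tile_class"]) == {"non_tumor"}

    def test_full_slide_epithelium_has_im_ring(self):
        # epithelium everywhere: the slide edge is the tumor boundary, so the
        # outermost tile ring is IM and the interior tiles TC
        shape = (875, 875)  # 7 x 7 mm at 8 um/px -> 5 x 5 tiles
        epi = np.ones(shape, bool)
        s = make_sample(cell_frame([], [], []), shape=shape, um_per_px=8.0,
                        epithelium=epi)
        grid = classify_tiles(build_tile_grid(s), epi, im_band_um=500.0)
        t = grid.tiles
        edge = (
            (t["ix"] == 0) | (t["iy"] == 0)
            | (t["ix"] == t["ix"].max()) | (t["iy"] == t["iy"].max())
        )
        assert (t.loc[edge, "tile_class"] == "IM").all()
        assert (t.loc[~edge, "tile_class"] == "TC").all()

    def test_disc_tumor_matches_distance_oracle(self):
        # solid epithelium disc; with a 1 px closing the tumor region is the
        # disc itself, so the IM set can be recomputed by brute-force
        # distances to the region complement
        shape = (300, 300)
        px = 20.0
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        r = np.hypot((xx + 0.5) * px - 3000.0, (yy + 0.5) * px - 3000.0)
        disc = r <= 2000.0
        s = make_sample(cell_frame([], [], []), shape=shape, um_per_px=px,
                        epithelium=disc)
        grid = build_tile_grid(s)
        got = classify_tiles(grid, disc, im_band_um=500.0, closing_radius_um=px)

        # nearest background pixel always lies on the contour adjacent to the
        # disc, so brute-force distances only against that layer
        contour = np.zeros(shape, bool)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                contour |= ~disc & np.roll(np.roll(disc, dy, 0), dx, 1)
        bg = np.argwhere(contour)
        fg = np.argwhere(disc)
        dist = np.zeros(shape)
        for chunk in np.array_split(fg, 40):
            d2 = ((chunk[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2).min(axis=1)
            dist[tuple(chunk.T)] = np.sqrt(d2) * px
        band = disc & (dist <= 500.0)

        for _, t in got.tiles.iterrows():
            r0 = int(t["y0_um"] / px)
            c0 = int(t["x0_um"] / px)
            side = int(round(got.side_um / px))
            win_epi = disc[r0:r0 + side, c0:c0 + side]
            win_band = band[r0:r0 + side, c0:c0 + side]
            if not win_epi.any():
                assert t["tile_class"] == "non_tumor"
            elif win_band.any():
                assert t["tile_class"] == "IM"
            else:
                assert t["tile_class"] == "TC"


class TestAssignCompartments:
    def _fixture(self):
        shape = (400, 400)
        epi = np.zeros(shape, bool)
        epi[0:100, 0:100] = True  # epithelium in the first tile
        cells = cell_frame(
            [100.0, 900.0, 2500.0, 99999.0],
            [100.0, 900.0, 2500.0, 100.0],
            ["CD8", "FOXP3", "PD1", "CD8"],
        )
        s = make_sample(cells, shape=shape, um_per_px=8.0, epithelium=epi)
        grid = classify_tiles(build_tile_grid(s), epi, closing_radius_um=100.0)
        return s, grid

    def test_compartment_rules_and_dropping(self):
        s, grid = self._fixture()
        out, dropped = assign_compartments(s.cells, s.epithelium_mask, grid)
        assert dropped == 1  # the far-away cell
        by_pheno = out.set_index("phenotype")
        assert by_pheno.loc["CD8", "compartment"] == "tumor_epithelium"
        assert by_pheno.loc["FOXP3", "compartment"] == "tumor_stroma"
        assert by_pheno.loc["PD1", "compartment"] == "non_tumor_stroma"

    def test_matches_pointwise_lookup_oracle(self, rng, inflamed_sample):
        s = inflamed_sample
        grid = classify_tiles(build_tile_grid(s), s.epithelium_mask)
        out, _ = assign_compartments(s.cells, s.epithelium_mask, grid)
        tile_class = {(r["ix"], r["iy"]): r["tile_class"]
                      for _, r in grid.tiles.iterrows()}
        idx = rng.choice(len(out), size=200, replace=False)
        for i in idx:
            row = out.iloc[i]
            col = int(row["x_um"] / s.um_per_px)
            rr = int(row["y_um"] / s.um_per_px)
            ix = int((row["x_um"] - grid.origin_um[0]) // grid.side_um)
            iy = int((row["y_um"] - grid.origin_um[1]) // grid.side_um)
            if s.epithelium_mask[rr, col]:
                want = "tumor_epithelium"
            elif tile_class[(ix, iy)] == "non_tumor":
                want = "non_tumor_stroma"
            else:
                want = "tumor_stroma"
            assert row["compartment"] == want


class TestComputeDensities:
    def test_single_tile_arithmetic(self):
        # one tile; epithelium strip of 0.5 mm^2 holding 150 CD8 cells
        shape = (177, 177)  # 1416 um at 8 um/px -> single 2 mm^2 tile
        epi = np.zeros(shape, bool)
        epi[0:88, 0:88] = True  # 0.704 x 0.704 mm = 0.4956 mm^2
        rng = np.random.default_rng(0)
        xs = rng.uniform(0, 700, 150)
        ys = rng.uniform(0, 700, 150)
        cells = cell_frame(xs, ys, "CD8")
        s = make_sample(cells, shape=shape, um_per_px=8.0, epithelium=epi)
        grid = classify_tiles(build_tile_grid(s), epi, closing_radius_um=100.0)
        labelled, _ = assign_compartments(cells, epi, grid)
        labelled = labelled[labelled["compartment"] == "tumor_epithelium"]
        d = compute_densities(labelled, grid)
        area = epi.sum() * (8.0 / 1000.0) ** 2
        want = len(labelled) / area
        got = d.table.query(
            "marker == 'CD8' and compartment == 'tumor_epithelium' and region == 'all'"
        )["density_cells_per_mm2"].iloc[0]
        assert got == pytest.approx(want)

    def test_zero_immune_cells(self, desert_sample):
        s = desert_sample
        grid = classify_tiles(build_tile_grid(s), s.epithelium_mask)
        cells, _ = assign_compartments(
            s.cells[s.cells["phenotype"] == "tumor"], s.epithelium_mask, grid
        )
        d = compute_densities(cells, grid)
        dens = d.table["density_cells_per_mm2"].dropna()
        assert (dens == 0).all()
        assert d.tc_combined == 0.0 and d.im_combined == 0.0
        assert not d.ratio_defined

    def test_matches_recount_oracle(self, inflamed_sample):
        s = inflamed_sample
        grid = classify_tiles(build_tile_grid(s), s.epithelium_mask)
        cells, _ = assign_compartments(s.cells, s.epithelium_mask, grid)
        d = compute_densities(cells, grid)

        # independent recount: pandas groupby over cells + tile areas
        areas = grid.tiles.set_index(["ix", "iy"])
        use = cells[~cells["multipositive"]
                    & cells["phenotype"].isin(("CD8", "FOXP3", "PD1"))]
        for marker in ("CD8", "FOXP3", "PD1"):
            for comp, area_of in (
                ("tumor_epithelium", lambda t: t["epithelium_area_mm2"]),
                ("tumor_stroma",
                 lambda t: t["tissue_area_mm2"] - t["epithelium_area_mm2"]),
            ):
                vals = []
                for (ix, iy), t in areas.iterrows():
                    if t["tile_class"] not in ("TC", "IM"):
                        continue
                    a = area_of(t)
                    if a <= 0:
                        continue
                    n = len(use[(use["phenotype"] == marker)
                                & (use["compartment"] == comp)
                                & (use["tile_ix"] == ix)
                                & (use["tile_iy"] == iy)])
                    vals.append(n / a)
                want = np.mean(vals)
                got = d.table.query(
                    "marker == @marker and compartment == @comp and region == 'all'"
                )["density_cells_per_mm2"].iloc[0]
                assert got == pytest.approx(want)

        # combined density is the sum of the three marker means
        for region in ("TC", "IM", "all"):
            parts = d.table.query(
                "compartment == 'tumor_epithelium' and region == @region"
            )["density_cells_per_mm2"]
            assert d.combined[("tumor_epithelium", region)] == pytest.approx(
                parts.sum()
            )

    def test_multipositive_cells_excluded(self):
        shape = (177, 177)
        cells = pd.concat([
            cell_frame([100.0] * 10, [100.0] * 10, "CD8"),
            cell_frame([200.0] * 5, [200.0] * 5, "CD8", multipositive=True),
        ], ignore_index=True)
        epi = np.ones(shape, bool)
        s = make_sample(cells, shape=shape, um_per_px=8.0, epithelium=epi)
        grid = classify_tiles(build_tile_grid(s), epi)
        labelled, _ = assign_compartments(cells, epi, grid)
        d = compute_densities(labelled, grid)
        total = d.per_tile["CD8_per_mm2"].iloc[0] * d.per_tile["tissue_area_mm2"].iloc[0]
        assert total == pytest.approx(10)

    def test_adding_cell_never_decreases_density(self, desert_sample):
        s = desert_sample
        grid = classify_tiles(build_tile_grid(s), s.epithelium_mask)
        cells, _ = assign_compartments(s.cells, s.epithelium_mask, grid)
        d0 = compute_densities(cells, grid)
        extra = cells[cells["compartment"] == "tumor_stroma"].iloc[[0]].copy()
        extra["phenotype"] = "CD8"
        d1 = compute_densities(pd.concat([cells, extra], ignore_index=True), grid)
        q = "marker == 'CD8' and compartment == 'tumor_stroma' and region == 'all'"
        assert (d1.table.query(q)["density_cells_per_mm2"].iloc[0]
                >= d0.table.query(q)["density_cells_per_mm2"].iloc[0])


class TestHeatmapAndDeltas:
    def test_heatmap_matches_per_tile_lookup(self, inflamed_sample):
        s = inflamed_sample
        grid = classify_tiles(build_tile_grid(s), s.epithelium_mask)
        cells, _ = assign_compartments(s.cells, s.epithelium_mask, grid)
        d = compute_densities(cells, grid)
        mat = density_heatmap(grid, d, "CD8")
        assert mat.shape == (grid.ny, grid.nx)
        for _, t in d.per_tile.iterrows():
            assert mat[int(t["iy"]), int(t["ix"])] == pytest.approx(t["CD8_per_mm2"])
        with pytest.raises(ValueError):
            density_heatmap(grid, d, "CD4")

    def test_paired_delta(self, inflamed_sample, desert_sample):
        def dens(s):
            grid = classify_tiles(build_tile_grid(s), s.epithelium_mask)
            cells, _ = assign_compartments(s.cells, s.epithelium_mask, grid)
            return compute_densities(cells, grid)

        a, b = dens(inflamed_sample), dens(desert_sample)
        zero = paired_delta(a, a)
        assert (zero["delta_cells_per_mm2"].dropna() == 0).all()
        d = paired_delta(b, a).set_index(["marker", "compartment", "region"])
        at = a.table.set_index(["marker", "compartment", "region"])
        bt = b.table.set_index(["marker", "compartment", "region"])
        ref = at["density_cells_per_mm2"] - bt["density_cells_per_mm2"]
        pd.testing.assert_series_equal(
            d["delta_cells_per_mm2"], ref.rename("delta_cells_per_mm2")
        )
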