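"""File dialects: cell tables, masks, outcome tables, metrics, grids."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

CELL_COLUMNS = ["sample_id", "x_um", "y_um", "phenotype", "pdl1", "multipositive"]
OUTCOME_COLUMNS = ["patient_id", "trg", "os_months", "event", "sample_type"]


def write_cells(cells: pd.DataFrame, sample_id: str, path) -> None:
    out = cells.copy()
    out.insert(0, "sample_id", sample_id)
    out[CELL_COLUMNS].to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    df["pdl1"] = df["pdl1"].astype(bool)
    df["multipositive"] = df["multipositive"].astype(bool)
    return df


def write_mask(mask: np.ndarray, um_per_px: float, path) -> None:
    """Single-channel TIFF plus a JSON sidecar recording the resolution."""
    path = Path(path)
    tifffile.imwrite(path, mask.astype(np.uint8))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"um_per_px": um_per_px}))


def read_mask(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    mask = tifffile.imread(path).astype(bool)
    sidecar = path.with_suffix(path.suffix + ".json")
    um_per_px = json.loads(sidecar.read_text())["um_per_px"]
    return mask, float(um_per_px)


def write_outcomes(records, path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "trg": r.trg,
            "os_months": r.os_months,
            "event": int(r.event),
            "sample_type": "biopsy",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=OUTCOME_COLUMNS).to_csv(path, index=False)


def write_metrics(table: pd.DataFrame, sample_id: str, path) -> None:
    out = table.copy()
    out.insert(0, "sample_id", sample_id)
    out.to_csv(path, index=False)


def grid_to_json(grid) -> dict:
    """Tile rectangles with classes, GeoJSON-like."""
    feats = []
    for _, t in grid.tiles.iterrows():
        feats.append(
            {
                "ix": int(t["ix"]),
                "iy": int(t["iy"]),
                "x0_um": float(t["x0_um"]),
                "y0_um": float(t["y0_um"]),
                "side_um": float(grid.side_um),
                "tile_class": t["tile_class"],
                "tissue_area_mm2": float(t["tissue_area_mm2"]),
                "epithelium_area_mm2": float(t["epithelium_area_mm2"]),
            }
        )
    return {"origin_um": list(grid.origin_um), "side_um": grid.side_um,
            "nx": grid.nx, "ny": grid.ny, "tiles": feats}


def write_stats_report(rows: list[dict], path) -> None:
    cols = ["analysis", "exposure", "outcome", "estimate", "ci_low", "ci_high",
            "p", "method", "n"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
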