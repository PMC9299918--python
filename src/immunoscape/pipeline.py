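"""End-to-end orchestration: sample quantification and cohort analysis.

``run_sample`` chains the spatial stages (tile grid, TC/IM classification,
compartment assignment, densities, landscape label, CPS) for one sample;
``run_cohort`` maps it over a cohort and ``associate`` computes every
reported statistic from the per-patient table alone, so each number in a
report is recomputable from the emitted CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iomod
from .scoring import (
    LandscapeLabel,
    LandscapeThresholds,
    PatientRecord,
    classify_landscape,
    combined_positive_score,
)
from .spatial import (
    CompartmentDensities,
    assign_compartments,
    build_tile_grid,
    classify_tiles,
    compute_densities,
    paired_delta,
)
from .stats import fisher_exact, km_logrank, odds_ratio, signed_rank, trend_test
from .synthetic import IMMUNE_MARKERS, TissueSample

PER_PATIENT_COLUMNS = [
    "patient_id", "landscape", "tc_density", "im_density", "ratio",
    "cps", "cps_ge1", "cps_ge10", "trg", "os_months", "event",
]


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis; defaults are the study values
    (2 mm^2 tiles, IM band 500 um, landscape cut-offs 75/400/0.5, CPS
    evaluable from 100 tumor cells on the x100 clinical scale)."""

    tile_area_mm2: float = 2.0
    min_tissue_fraction: float = 0.1
    im_band_um: float = 500.0
    closing_radius_um: float = 800.0
    thresholds: LandscapeThresholds = field(default_factory=LandscapeThresholds)
    cps_scale: str = "clinical"
    min_tumor_cells: int = 100
    autothreshold: str = "otsu"
    merge_radius_um: float = 5.0
    tile_average: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.tile_area_mm2 <= 0 or self.im_band_um <= 0:
            raise ValueError("tile_area and im_band must be positive")
        if not 0 <= self.min_tissue_fraction < 1:
            raise ValueError("min_tissue_fraction must be in [0, 1)")
        if self.cps_scale not in ("clinical", "raw"):
            raise ValueError("cps_scale must be 'clinical' or 'raw'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        thr = data.pop("thresholds", None)
        cfg = cls(**data)
        if thr is not None:
            cfg = dataclasses.replace(cfg, thresholds=LandscapeThresholds(**thr))
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def manifest(self) -> dict:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return {
            "config": self.to_dict(),
            "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
        }


@dataclass
class SampleMetrics:
    sample_id: str
    sample_type: str
    densities: CompartmentDensities
    landscape: LandscapeLabel | None
    cps: object
    n_cells: int
    n_dropped: int
    manifest: dict


def run_sample(sample: TissueSample, config: PipelineConfig | None = None) -> SampleMetrics:
    """Quantify one sample: tiles, compartments, densities, landscape, CPS."""
    config = config or PipelineConfig()
    config.validate()

    grid = build_tile_grid(
        sample, tile_area_mm2=config.tile_area_mm2,
        min_tissue_fraction=config.min_tissue_fraction,
    )
    grid = classify_tiles(
        grid, sample.epithelium_mask,
        im_band_um=config.im_band_um, closing_radius_um=config.closing_radius_um,
    )
    cells, n_dropped = assign_compartments(sample.cells, sample.epithelium_mask, grid)
    dens = compute_densities(cells, grid, tile_average=config.tile_average)

    landscape = classify_landscape(dens.tc_combined, dens.im_combined, config.thresholds)

    tumor = cells[cells["phenotype"] == "tumor"]
    immune = cells[cells["phenotype"].isin(IMMUNE_MARKERS) & ~cells["multipositive"]]
    cps = combined_positive_score(
        int(tumor["pdl1"].sum()), int(immune["pdl1"].sum()), len(tumor),
        scale=config.cps_scale, min_tumor_cells=config.min_tumor_cells,
    )

    manifest = config.manifest()
    manifest["sample_id"] = sample.sample_id
    return SampleMetrics(
        sample_id=sample.sample_id,
        sample_type=sample.sample_type,
        densities=dens,
        landscape=landscape,
        cps=cps,
        n_cells=len(cells),
        n_dropped=n_dropped,
        manifest=manifest,
    )


def _metrics_row(rec: PatientRecord) -> dict:
    row = {
        "patient_id": rec.patient_id,
        "trg": rec.trg,
        "os_months": rec.os_months,
        "event": int(rec.event),
        "truth_pattern": rec.truth_pattern,
        "landscape": math.nan,
        "tc_density": math.nan,
        "im_density": math.nan,
        "ratio": math.nan,
        "cps": math.nan,
        "cps_ge1": math.nan,
        "cps_ge10": math.nan,
        "biopsy_combined_density": math.nan,
    }
    if rec.cps_biopsy is not None:
        row["cps"] = rec.cps_biopsy.cps
        row["cps_ge1"] = int(rec.cps_biopsy.cps_ge1)
        row["cps_ge10"] = int(rec.cps_biopsy.cps_ge10)
    if rec.landscape is not None:
        row["landscape"] = rec.landscape.label
        row["tc_density"] = rec.landscape.tc_density
        row["im_density"] = rec.landscape.im_density
        row["ratio"] = rec.landscape.tc_im_ratio
    if rec.truth_combined_density is not None:
        row["biopsy_combined_density"] = rec.truth_combined_density
    return row


def cohort_table(records: list[PatientRecord]) -> pd.DataFrame:
    """Per-patient analysis table (one row per patient)."""
    return pd.DataFrame([_metrics_row(r) for r in records])


def run_cohort(
    records: list[PatientRecord],
    config: PipelineConfig | None = None,
    quantify_tissue: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Quantify every patient's samples and compute the cohort statistics.

    Patients with TRG 1 (complete regression: no vital tumor in the
    resection) contribute no resection landscape.  With
    ``quantify_tissue=False`` only the outcome/CPS structure already present
    on the records is analysed (fast path for large simulated cohorts).
    """
    if len(records) < 2:
        raise ValueError("cohort needs at least 2 patients")
    config = config or PipelineConfig()

    for rec in records:
        if not quantify_tissue:
            continue
        if rec.resection is not None and rec.resection_evaluable:
            m = run_sample(rec.resection, config)
            rec.resection_metrics = m.densities
            rec.landscape = m.landscape
            rec.cps_resection = m.cps
        if rec.biopsy is not None:
            m = run_sample(rec.biopsy, config)
            rec.biopsy_metrics = m.densities
            if rec.cps_biopsy is None:
                rec.cps_biopsy = m.cps

    table = cohort_table(records)
    report = associate(table)

    # paired biopsy-resection deltas (tissue-based runs only)
    paired = [
        r for r in records
        if r.biopsy_metrics is not None and r.resection_metrics is not None
    ]
    if paired:
        deltas = {}
        for marker in IMMUNE_MARKERS:
            vals = []
            for r in paired:
                d = paired_delta(r.biopsy_metrics, r.resection_metrics)
                v = d[
                    (d["marker"] == marker)
                    & (d["compartment"] == "tumor_epithelium")
                    & (d["region"] == "all")
                ]["delta_cells_per_mm2"]
                if len(v):
                    vals.append(float(v.iloc[0]))
            vals = [v for v in vals if not math.isnan(v)]
            if vals:
                deltas[marker] = signed_rank(vals)
        report["paired_epithelium_deltas"] = deltas
    return table, report


def associate(table: pd.DataFrame) -> dict:
    """All cohort statistics from the per-patient table alone.

    Produces the landscape frequency table, the 2x2 odds-ratio and Fisher
    tests of CPS cut-offs against histopathological response (Mandard TRG
    1-3 vs 4-5), the density-response trend test, and Kaplan-Meier /
    log-rank comparisons by CPS and by landscape.
    """
    report: dict = {}
    t = table.copy()
    t["response_poor"] = (t["trg"] >= 4).astype(int)

    if t["landscape"].notna().any():
        freq = t["landscape"].dropna().value_counts()
        report["landscape_frequency"] = freq.to_dict()
        report["landscape_fraction"] = (freq / freq.sum()).to_dict()

    for flag in ("cps_ge1", "cps_ge10"):
        sub = t[t[flag].notna()]
        if len(sub) == 0:
            continue
        a = int(((sub[flag] == 0) & (sub["response_poor"] == 0)).sum())
        b = int(((sub[flag] == 0) & (sub["response_poor"] == 1)).sum())
        c = int(((sub[flag] == 1) & (sub["response_poor"] == 0)).sum())
        d = int(((sub[flag] == 1) & (sub["response_poor"] == 1)).sum())
        tab = [[a, b], [c, d]]
        try:
            report[f"or_{flag}"] = odds_ratio(tab)
        except ValueError:
            report[f"or_{flag}"] = None
        report[f"fisher_{flag}"] = fisher_exact(tab)
        report[f"table_{flag}"] = tab

    dens = t["biopsy_combined_density"]
    if dens.notna().sum() >= 4 and t["trg"].nunique() >= 3:
        high = (dens >= dens.median()).astype(int)
        k = int(t["trg"].max())
        counts = np.zeros((2, k), dtype=int)
        for row, grp in zip(t["trg"], high):
            counts[grp, int(row) - 1] += 1
        keep = counts.sum(axis=0) > 0
        try:
            report["trend_density_trg"] = trend_test(
                counts[:, keep], col_scores=np.arange(1, k + 1)[keep]
            )
        except ValueError:
            report["trend_density_trg"] = None

    sub = t[t["cps_ge1"].notna()]
    if len(sub) >= 4 and sub["cps_ge1"].nunique() == 2:
        curves, medians, test = km_logrank(
            sub["os_months"], sub["event"].astype(bool), sub["cps_ge1"].astype(int)
        )
        report["km_by_cps_ge1"] = {"medians": medians, "test": test}
    sub = t[t["landscape"].notna()]
    if len(sub) >= 4 and sub["landscape"].nunique() >= 2:
        curves, medians, test = km_logrank(
            sub["os_months"], sub["event"].astype(bool), sub["landscape"]
        )
        report["km_by_landscape"] = {"medians": medians, "test": test}
    return report


def report_rows(report: dict) -> list[dict]:
    """Flatten an `associate` report into the tidy statistics CSV dialect."""
    rows = []

    def add(analysis, exposure, outcome, tr):
        if tr is None:
            return
        rows.append(
            {
                "analysis": analysis,
                "exposure": exposure,
                "outcome": outcome,
                "estimate": getattr(tr, "estimate", math.nan),
                "ci_low": getattr(tr, "ci_low", math.nan),
                "ci_high": getattr(tr, "ci_high", math.nan),
                "p": getattr(tr, "p_value", math.nan),
                "method": getattr(tr, "method", ""),
                "n": getattr(tr, "n", 0),
            }
        )

    for flag in ("cps_ge1", "cps_ge10"):
        add("univariate_or", flag, "trg_4_5", report.get(f"or_{flag}"))
        add("fisher", flag, "trg_4_5", report.get(f"fisher_{flag}"))
    add("trend", "combined_density_high", "trg_ordinal", report.get("trend_density_trg"))
    for key in ("km_by_cps_ge1", "km_by_landscape"):
        if key in report:
            add("logrank", key.replace("km_by_", ""), "os", report[key]["test"])
    for marker, tr in report.get("paired_epithelium_deltas", {}).items():
        add("signed_rank", marker, "resection_minus_biopsy", tr)
    return rows


def write_sample_outputs(metrics: SampleMetrics, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iomod.write_metrics(
        metrics.densities.table, metrics.sample_id, out / f"{metrics.sample_id}_metrics.csv"
    )
    (out / f"{metrics.sample_id}_manifest.json").write_text(
        json.dumps(metrics.manifest, sort_keys=True, default=str, indent=2)
    )
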