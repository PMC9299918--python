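"""Seeded synthetic tissue, biopsy and cohort generation.

This module emulates the inputs of a multiplex-IHC spatial analysis of
esophageal adenocarcinoma: per-sample cell maps (CD8+, FOXP3+, PD-1+
tumor-associated immune cells, pan-cytokeratin+ tumor cells), an epithelium
mask, biopsy fragmentation, and cohort-level outcome structure (Mandard
tumor-regression grade, overall survival with censoring).

The spatial model is an inhomogeneous Poisson point process with
piecewise-constant intensity over three concentric regions of a disc-shaped
tumor: the tumor interior, a margin band straddling the tumor boundary, and
the surrounding non-tumor tissue.  The three canonical immune-landscape
patterns differ only in those intensities:

* ``inflamed`` — high immune intensity throughout the tumor;
* ``invasive_margin`` — immune cells confined to the margin band;
* ``desert`` — low intensity everywhere.

Tumor (epithelial) cells fill a blob-shaped pan-cytokeratin+ mask at a fixed
packing density.  All outputs are deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .scoring import PatientRecord, combined_positive_score

# --------------------------------------------------------------------------
# constants: markers, patterns and their default study conditions
# --------------------------------------------------------------------------

IMMUNE_MARKERS: tuple[str, ...] = ("CD8", "FOXP3", "PD1")
PHENOTYPES: tuple[str, ...] = IMMUNE_MARKERS + ("tumor", "other")
PATTERNS: tuple[str, ...] = ("inflamed", "invasive_margin", "desert")

#: combined immune intensity (cells/mm^2) by (interior, margin band, outside)
PATTERN_COMBINED_INTENSITY: dict[str, tuple[float, float, float]] = {
    "inflamed": (300.0, 300.0, 20.0),
    "invasive_margin": (10.0, 800.0, 20.0),
    "desert": (10.0, 20.0, 5.0),
}

#: fraction of the combined immune intensity carried by each marker
DEFAULT_MARKER_FRACTIONS: dict[str, float] = {"CD8": 0.5, "FOXP3": 0.25, "PD1": 0.25}

REGIONS: tuple[str, ...] = ("interior", "margin", "outside")


@dataclass(frozen=True)
class TissueGeometry:
    """Geometry of a synthetic resection specimen.

    The tumor is a disc of radius ``tumor_radius_um`` centred in a
    rectangular, fully tissue-covered slide of size ``extent_um``.  The
    margin band extends ``margin_band_um`` to either side of the disc
    boundary.  Epithelium blobs (smoothed thresholded noise at spatial scale
    ``blob_scale_um``) occupy ``epithelium_fraction`` of the tumor disc.
    """

    extent_um: tuple[float, float] = (8000.0, 8000.0)
    tumor_radius_um: float = 3000.0
    margin_band_um: float = 700.0
    epithelium_fraction: float = 0.30
    blob_scale_um: float = 150.0
    um_per_px: float = 2.0
    tumor_packing_per_mm2: float = 1000.0
    other_cell_per_mm2: float = 50.0


@dataclass
class TissueSample:
    """A synthetic (or imported) tissue sample.

    ``cells`` is a table with columns ``x_um, y_um, phenotype, pdl1,
    multipositive`` — compartment and tile labels are assigned downstream by
    the spatial-quantification stage, never at generation time.
    """

    sample_id: str
    sample_type: str  # "biopsy" | "resection"
    cells: pd.DataFrame
    epithelium_mask: np.ndarray
    tissue_mask: np.ndarray
    um_per_px: float
    truth_pattern: str = "none"
    truth_params: dict = field(default_factory=dict)

    @property
    def extent_um(self) -> tuple[float, float]:
        ny, nx = self.tissue_mask.shape
        return (nx * self.um_per_px, ny * self.um_per_px)


def pattern_densities(
    pattern: str,
    marker_fractions: Mapping[str, float] | None = None,
    combined: tuple[float, float, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-marker, per-region intensities (cells/mm^2) for a named pattern."""
    fractions = dict(marker_fractions or DEFAULT_MARKER_FRACTIONS)
    if combined is None:
        if pattern not in PATTERN_COMBINED_INTENSITY:
            raise ValueError(
                f"pattern {pattern!r} has no default intensities; pass `combined`"
            )
        combined = PATTERN_COMBINED_INTENSITY[pattern]
    return {
        m: {r: f * combined[i] for i, r in enumerate(REGIONS)}
        for m, f in fractions.items()
    }


# --------------------------------------------------------------------------
# single-sample generation
# --------------------------------------------------------------------------


def _sample_points_in_mask(
    rng: np.random.Generator, mask: np.ndarray, n: int, um_per_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """n points uniform over the foreground of a raster mask (coords in um)."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0 or n == 0:
        return np.empty(0), np.empty(0)
    idx = rng.integers(0, rows.size, size=n)
    x = (cols[idx] + rng.random(n)) * um_per_px
    y = (rows[idx] + rng.random(n)) * um_per_px
    return x, y


def _region_masks(
    shape: tuple[int, int], geometry: TissueGeometry
) -> dict[str, np.ndarray]:
    ny, nx = shape
    px = geometry.um_per_px
    cx, cy = geometry.extent_um[0] / 2.0, geometry.extent_um[1] / 2.0
    xs = (np.arange(nx) + 0.5) * px
    ys = (np.arange(ny) + 0.5) * px
    r = np.hypot(xs[None, :] - cx, ys[:, None] - cy)
    R, band = geometry.tumor_radius_um, geometry.margin_band_um
    return {
        "disc": r <= R,
        "interior": r < R - band,
        "margin": np.abs(r - R) <= band,
        "outside": r > R + band,
    }


def _epithelium_blobs(
    rng: np.random.Generator, disc: np.ndarray, geometry: TissueGeometry
) -> np.ndarray:
    """Smoothed-noise blobs occupying `epithelium_fraction` of the disc."""
    if geometry.epithelium_fraction <= 0 or not disc.any():
        return np.zeros_like(disc)
    if geometry.epithelium_fraction >= 1:
        return disc.copy()
    # smoothed noise generated on a coarse lattice (~blob_scale/4) and
    # upsampled: identical structure, far cheaper than full-resolution filtering
    coarse_um = max(geometry.um_per_px, geometry.blob_scale_um / 4.0)
    factor = coarse_um / geometry.um_per_px
    cshape = (
        max(2, int(math.ceil(disc.shape[0] / factor))),
        max(2, int(math.ceil(disc.shape[1] / factor))),
    )
    noise = rng.standard_normal(cshape)
    smooth_c = gaussian_filter(noise, sigma=geometry.blob_scale_um / coarse_um)
    from scipy.ndimage import zoom

    smooth = zoom(
        smooth_c,
        (disc.shape[0] / cshape[0], disc.shape[1] / cshape[1]),
        order=1,
        grid_mode=True,
        mode="nearest",
    )[: disc.shape[0], : disc.shape[1]]
    thr = np.quantile(smooth[disc], 1.0 - geometry.epithelium_fraction)
    return disc & (smooth >= thr)


def generate_tissue(
    pattern: str,
    geometry: TissueGeometry | None = None,
    densities: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    sample_id: str | None = None,
    pdl1_tumor_rate: float = 0.05,
    pdl1_immune_rate: float = 0.10,
    multipositive_rate: float = 0.0,
) -> TissueSample:
    """Generate one resection-type sample with a known ground-truth pattern.

    Parameters
    ----------
    pattern
        One of ``inflamed``, ``invasive_margin``, ``desert`` (defaults looked
        up per pattern) or ``none`` (then `densities` must be given).
    densities
        ``{marker: {interior, margin, outside}}`` intensities in cells/mm^2;
        overrides the pattern defaults.
    """
    geometry = geometry or TissueGeometry()
    w, h = geometry.extent_um
    if w <= 0 or h <= 0:
        raise ValueError("extent must be positive")
    min_extent = 4 * math.sqrt(2.0) * 1000.0  # four 2-mm^2 tiles per direction
    if min(w, h) < min_extent:
        raise ValueError(
            f"resection extent must be at least {min_extent:.0f} um per direction"
        )
    if pattern == "none" and densities is None:
        raise ValueError("pattern 'none' requires explicit densities")
    if densities is None:
        densities = pattern_densities(pattern)
    for m, per_region in densities.items():
        for r, v in per_region.items():
            if v < 0:
                raise ValueError(f"negative intensity for {m}/{r}")

    rng = np.random.default_rng(seed)
    px = geometry.um_per_px
    shape = (int(round(h / px)), int(round(w / px)))
    px_area_mm2 = (px / 1000.0) ** 2

    regions = _region_masks(shape, geometry)
    tissue = np.ones(shape, dtype=bool)
    epithelium = _epithelium_blobs(rng, regions["disc"], geometry)

    frames: list[pd.DataFrame] = []
    for marker in densities:
        for region in REGIONS:
            intensity = float(densities[marker].get(region, 0.0))
            mask = regions[region] & tissue
            area = mask.sum() * px_area_mm2
            n = rng.poisson(intensity * area)
            x, y = _sample_points_in_mask(rng, mask, n, px)
            if x.size:
                frames.append(
                    pd.DataFrame(
                        {
                            "x_um": x,
                            "y_um": y,
                            "phenotype": marker,
                            "pdl1": rng.random(x.size) < pdl1_immune_rate,
                            "multipositive": rng.random(x.size) < multipositive_rate,
                        }
                    )
                )

    epi_area = epithelium.sum() * px_area_mm2
    n_tumor = rng.poisson(geometry.tumor_packing_per_mm2 * epi_area)
    tx, ty = _sample_points_in_mask(rng, epithelium, n_tumor, px)
    if tx.size:
        frames.append(
            pd.DataFrame(
                {
                    "x_um": tx,
                    "y_um": ty,
                    "phenotype": "tumor",
                    "pdl1": rng.random(tx.size) < pdl1_tumor_rate,
                    "multipositive": False,
                }
            )
        )

    tissue_area = tissue.sum() * px_area_mm2
    n_other = rng.poisson(geometry.other_cell_per_mm2 * tissue_area)
    ox, oy = _sample_points_in_mask(rng, tissue, n_other, px)
    if ox.size:
        frames.append(
            pd.DataFrame(
                {
                    "x_um": ox,
                    "y_um": oy,
                    "phenotype": "other",
                    "pdl1": False,
                    "multipositive": False,
                }
            )
        )

    if frames:
        cells = pd.concat(frames, ignore_index=True)
    else:
        cells = pd.DataFrame(
            columns=["x_um", "y_um", "phenotype", "pdl1", "multipositive"]
        ).astype({"x_um": float, "y_um": float, "pdl1": bool, "multipositive": bool})

    return TissueSample(
        sample_id=sample_id or f"{pattern}_{seed}",
        sample_type="resection",
        cells=cells,
        epithelium_mask=epithelium,
        tissue_mask=tissue,
        um_per_px=px,
        truth_pattern=pattern,
        truth_params={
            "seed": int(seed),
            "geometry": geometry,
            "densities": {m: dict(v) for m, v in densities.items()},
        },
    )


# --------------------------------------------------------------------------
# biopsy subsampling
# --------------------------------------------------------------------------


def generate_biopsy(
    parent: TissueSample,
    n_fragments: int = 4,
    fragment_extent_um: float = 1500.0,
    seed: int = 0,
    gap_um: float = 100.0,
) -> TissueSample:
    """Subsample a resection into a fragmented biopsy.

    ``n_fragments`` square crops of side ``fragment_extent_um`` are taken at
    random positions (centred on the tumor disc when the parent records one)
    and re-composed side by side, separated by non-tissue gaps.  Cells and
    mask pixels inside each crop window are conserved.
    """
    if parent.sample_type != "resection":
        raise ValueError("biopsies are generated from resection samples")
    w, h = parent.extent_um
    f = float(fragment_extent_um)
    if f > w or f > h:
        raise ValueError("fragment_extent larger than parent extent")
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")

    rng = np.random.default_rng(seed)
    px = parent.um_per_px
    fpx = int(round(f / px))
    gpx = int(round(gap_um / px))

    geometry: TissueGeometry | None = parent.truth_params.get("geometry")
    if geometry is not None:
        cx, cy, R = w / 2.0, h / 2.0, geometry.tumor_radius_um
    else:
        cx, cy, R = w / 2.0, h / 2.0, min(w, h) / 2.0

    windows: list[tuple[float, float]] = []
    for _ in range(n_fragments):
        # fragment centre uniform in the tumor disc, window clipped to slide
        theta = rng.uniform(0, 2 * math.pi)
        rad = R * math.sqrt(rng.random())
        fx = np.clip(cx + rad * math.cos(theta) - f / 2.0, 0.0, w - f)
        fy = np.clip(cy + rad * math.sin(theta) - f / 2.0, 0.0, h - f)
        windows.append((float(fx), float(fy)))

    out_h = fpx
    out_w = n_fragments * fpx + (n_fragments - 1) * gpx
    tissue = np.zeros((out_h, out_w), dtype=bool)
    epithelium = np.zeros((out_h, out_w), dtype=bool)

    cells = parent.cells
    frames: list[pd.DataFrame] = []
    for k, (fx, fy) in enumerate(windows):
        r0, c0 = int(round(fy / px)), int(round(fx / px))
        oc = k * (fpx + gpx)
        tissue[:, oc : oc + fpx] = parent.tissue_mask[r0 : r0 + fpx, c0 : c0 + fpx]
        epithelium[:, oc : oc + fpx] = parent.epithelium_mask[
            r0 : r0 + fpx, c0 : c0 + fpx
        ]
        inside = (
            (cells["x_um"] >= fx)
            & (cells["x_um"] < fx + f)
            & (cells["y_um"] >= fy)
            & (cells["y_um"] < fy + f)
        )
        sub = cells.loc[inside].copy()
        sub["x_um"] = sub["x_um"] - fx + oc * px
        sub["y_um"] = sub["y_um"] - fy
        frames.append(sub)

    out_cells = (
        pd.concat(frames, ignore_index=True) if frames else cells.iloc[0:0].copy()
    )
    return TissueSample(
        sample_id=f"{parent.sample_id}_biopsy",
        sample_type="biopsy",
        cells=out_cells,
        epithelium_mask=epithelium,
        tissue_mask=tissue,
        um_per_px=px,
        truth_pattern=parent.truth_pattern,
        truth_params={
            "parent": parent.sample_id,
            "seed": int(seed),
            "windows": windows,
            "fragment_extent_um": f,
        },
    )


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Cohort-level generative model.

    ``trg_effect`` is the proportional-odds slope (log-odds of a *better*
    response per SD of combined biopsy immune density); ``survival_params``
    holds the baseline exponential median and the log hazard ratio per SD of
    the same density.  ``censoring_rate`` is the target fraction censored.
    """

    n_patients: int = 80
    pattern_mix: dict[str, float] = field(
        default_factory=lambda: {"inflamed": 0.56, "invasive_margin": 0.18, "desert": 0.26}
    )
    density_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(PATTERN_COMBINED_INTENSITY)
    )
    density_jitter_sd: float = 0.4
    trg_effect: float = 1.0
    cps_effect: float = 1.5
    survival_params: dict[str, float] = field(
        default_factory=lambda: {"baseline_median_months": 36.0, "log_hr_per_sd": -0.3}
    )
    censoring_rate: float = 0.3
    pdl1_positive_fraction: float = 0.2
    pdl1_tumor_rate_range: tuple[float, float] = (0.0, 0.10)
    pdl1_immune_rate_range: tuple[float, float] = (0.0, 0.25)
    trg_base_probs: tuple[float, ...] = (0.10, 0.20, 0.30, 0.25, 0.15)
    biopsy_tumor_cells_mean: float = 1500.0
    biopsy_area_mm2: float = 1.8
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        total = sum(self.pattern_mix.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("pattern_mix must sum to 1")
        if any(p < 0 for p in self.pattern_mix.values()):
            raise ValueError("pattern_mix probabilities must be >= 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        for v in self.density_params.values():
            if any(x < 0 for x in v):
                raise ValueError("intensities must be >= 0")


def _patient_rng(master_seed: int, index: int) -> np.random.Generator:
    """Stable per-patient stream derived from (master seed, patient index)."""
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF, int(index)])


def generate_cohort(
    spec: CohortSpec,
    with_tissue: bool = False,
    geometry: TissueGeometry | None = None,
) -> list[PatientRecord]:
    """Generate a cohort of patients with linked outcome structure.

    TRG (Mandard 1-5) is drawn from a proportional-odds model whose linear
    predictor combines the standardized combined biopsy density
    (slope ``trg_effect``) and centred CPS>=1 status (slope ``cps_effect``);
    both slopes act toward *better* response (lower TRG).  Overall survival
    is exponential with hazard scaled by ``exp(log_hr_per_sd * z)``;
    censoring is independent exponential calibrated to ``censoring_rate``.

    With ``with_tissue=True`` each record also carries a realized resection
    sample and a fragmented biopsy (slower; meant for modest cohort sizes).
    """
    spec.validate()
    patterns = list(spec.pattern_mix)
    probs = np.array([spec.pattern_mix[p] for p in patterns], dtype=float)

    mix_rng = np.random.default_rng([int(spec.master_seed) & 0x7FFFFFFF, 999_983])
    assigned = mix_rng.choice(len(patterns), size=spec.n_patients, p=probs)

    # pass 1: per-patient latent densities
    scales = np.empty(spec.n_patients)
    interior = np.empty(spec.n_patients)
    for i in range(spec.n_patients):
        rng = _patient_rng(spec.master_seed, i)
        sd = spec.density_jitter_sd
        scales[i] = math.exp(rng.normal(-0.5 * sd * sd, sd)) if sd > 0 else 1.0
        interior[i] = spec.density_params[patterns[assigned[i]]][0] * scales[i]

    mu, sigma = float(interior.mean()), float(interior.std())
    z = (interior - mu) / sigma if sigma > 0 else np.zeros_like(interior)

    cum = np.cumsum(spec.trg_base_probs)[:-1]
    alphas = logit(np.clip(cum, 1e-12, 1 - 1e-12))
    lam0 = math.log(2.0) / spec.survival_params["baseline_median_months"]
    log_hr = spec.survival_params.get("log_hr_per_sd", 0.0)
    c = spec.censoring_rate
    lam_c = lam0 * c / (1.0 - c) if c > 0 else 0.0
    # most patients express no PD-L1; `pdl1_positive_fraction` centres the
    # CPS term in the proportional-odds linear predictor
    p_cps = spec.pdl1_positive_fraction

    records: list[PatientRecord] = []
    for i in range(spec.n_patients):
        rng = _patient_rng(spec.master_seed, i)
        rng.normal()  # consume the jitter draw from pass 1 to stay aligned
        pattern = patterns[assigned[i]]

        # PD-L1 / CPS on the biopsy
        expresses = rng.random() < spec.pdl1_positive_fraction
        rate_t = rng.uniform(*spec.pdl1_tumor_rate_range) if expresses else 0.0
        rate_i = rng.uniform(*spec.pdl1_immune_rate_range) if expresses else 0.0
        n_tumor = int(rng.poisson(spec.biopsy_tumor_cells_mean))
        n_immune = int(rng.poisson(interior[i] * spec.biopsy_area_mm2))
        n_pdl1_t = int(rng.binomial(n_tumor, rate_t)) if n_tumor else 0
        n_pdl1_i = int(rng.binomial(n_immune, rate_i)) if n_immune else 0
        cps = combined_positive_score(n_pdl1_t, n_pdl1_i, n_tumor)

        # Mandard TRG from proportional odds (higher eta -> lower TRG)
        cps_ind = 1.0 if (cps.evaluable and cps.cps_ge1) else 0.0
        eta = spec.trg_effect * z[i] + spec.cps_effect * (cps_ind - p_cps)
        u = rng.random()
        cdf = expit(alphas + eta)
        trg = int(np.searchsorted(cdf, u) + 1)  # 1..5

        # overall survival
        lam = lam0 * math.exp(log_hr * z[i])
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.exponential(1.0 / lam_c) if lam_c > 0 else math.inf
        os_months = float(min(t_event, t_cens))
        event = bool(t_event <= t_cens)

        rec = PatientRecord(
            patient_id=f"P{i:04d}",
            trg=trg,
            os_months=os_months,
            event=event,
            cps_biopsy=cps,
            truth_pattern=pattern,
            truth_combined_density=float(interior[i]),
            resection_evaluable=trg != 1,
            seeds={"resection": int(rng.integers(0, 2**31 - 1)),
                   "biopsy": int(rng.integers(0, 2**31 - 1))},
        )

        if with_tissue:
            dens = pattern_densities(
                pattern, combined=tuple(v * scales[i] for v in spec.density_params[pattern])
            )
            resection = generate_tissue(
                pattern,
                geometry=geometry,
                densities=dens,
                seed=rec.seeds["resection"],
                sample_id=f"{rec.patient_id}_res",
                pdl1_tumor_rate=rate_t,
                pdl1_immune_rate=rate_i,
            )
            biopsy = generate_biopsy(resection, seed=rec.seeds["biopsy"])
            biopsy.sample_id = f"{rec.patient_id}_bx"
            rec.resection = resection
            rec.biopsy = biopsy
        records.append(rec)
    return records


# --------------------------------------------------------------------------
# multichromogen image rendering (inverse of the deconvolution stage)
# --------------------------------------------------------------------------

#: phenotype -> chromogen for the CD8/FOXP3/PD-1 triplex stain
TRIPLEX_CHANNEL_MAP: dict[str, str] = {
    "CD8": "vina_green",
    "FOXP3": "vulcan_red",
    "PD1": "dab",
}


def render_multiplex_image(
    sample: TissueSample,
    stains: "object | None" = None,
    um_per_px: float = 2.0,
    seed: int = 0,
    mode: str = "triplex",
    blob_radius_um: float = 4.0,
    amount: float = 1.0,
    noise_sd: float = 0.0,
    counterstain_od: float = 0.08,
):
    """Render a brightfield RGB image of a sample by Beer-Lambert composition.

    Each cell contributes a disc of chromogen optical density ``amount``;
    for ``mode="panck"`` the epithelium mask is rendered as a Vulcan-Red
    region instead (the pan-cytokeratin stain is applied to a separate
    section in the assay being emulated).  Transmitted RGB is
    ``exp(-sum_i amount_i * vector_i)`` plus counterstain background and
    optional additive Gaussian noise.
    """
    from .imaging import ChromogenImage, StainVectors

    stains = stains or StainVectors.defaults()
    w, h = sample.extent_um
    nx, ny = int(round(w / um_per_px)), int(round(h / um_per_px))
    rng = np.random.default_rng(seed)

    if mode == "triplex":
        channel_map = dict(TRIPLEX_CHANNEL_MAP)
    elif mode == "panck":
        channel_map = {"tumor": "vulcan_red"}
    else:
        raise ValueError(f"unknown render mode {mode!r}")
    for chromogen in channel_map.values():
        if chromogen not in stains.vectors:
            raise ValueError(f"no stain vector for chromogen {chromogen!r}")

    od = {c: np.zeros((ny, nx)) for c in set(channel_map.values())}

    if mode == "panck":
        from skimage.transform import resize

        scaled = resize(
            sample.epithelium_mask.astype(float), (ny, nx), order=0, anti_aliasing=False
        )
        od["vulcan_red"] += amount * (scaled > 0.5)
    else:
        rpx = max(1, int(round(blob_radius_um / um_per_px)))
        yy, xx = np.mgrid[-rpx : rpx + 1, -rpx : rpx + 1]
        kernel = (xx * xx + yy * yy <= rpx * rpx).astype(float) * amount
        for pheno, chromogen in channel_map.items():
            sub = sample.cells[sample.cells["phenotype"] == pheno]
            target = od[chromogen]
            for x, y in zip(sub["x_um"].to_numpy(), sub["y_um"].to_numpy()):
                cx, cy = int(x / um_per_px), int(y / um_per_px)
                r0, r1 = cy - rpx, cy + rpx + 1
                c0, c1 = cx - rpx, cx + rpx + 1
                kr0, kc0 = max(0, -r0), max(0, -c0)
                kr1 = kernel.shape[0] - max(0, r1 - ny)
                kc1 = kernel.shape[1] - max(0, c1 - nx)
                if kr0 >= kr1 or kc0 >= kc1:
                    continue
                target[max(0, r0) : min(ny, r1), max(0, c0) : min(nx, c1)] += kernel[
                    kr0:kr1, kc0:kc1
                ]

    od_rgb = np.zeros((ny, nx, 3))
    for chromogen, amap in od.items():
        od_rgb += amap[..., None] * stains.vectors[chromogen][None, None, :]
    if counterstain_od > 0:
        od_rgb += counterstain_od * stains.vectors["hematoxylin"][None, None, :]

    rgb = np.exp(-od_rgb)
    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)
    return ChromogenImage(rgb=rgb, um_per_px=um_per_px, channel_map=channel_map)
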