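"""Immune-landscape classification and PD-L1 / percent-positive scoring.

A tumor is assigned one of three immune-landscape patterns from the combined
mean TAIC density (CD8+ + FOXP3+ + PD-1+, cells/mm^2 of tissue) of its
tumor-center (TC) and invasive-margin (IM) tiles:

* **inflamed** — TC density >= 75;
* **invasive_margin** — TC density < 75, IM density >= 400 and TC/IM < 0.5;
* **desert** — low density in both compartments (everything else).

The combined positive score (CPS) follows the clinical convention:
``100 x (PD-L1+ tumor cells + PD-L1+ immune cells) / tumor cells``, evaluable
only in specimens with at least 100 vital tumor cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd


@dataclass(frozen=True)
class LandscapeThresholds:
    """Density cut-offs (cells/mm^2) defining the landscape patterns."""

    tc_high: float = 75.0
    im_high: float = 400.0
    ratio_cut: float = 0.5

    def __post_init__(self):
        if self.tc_high <= 0 or self.im_high <= 0 or self.ratio_cut <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class LandscapeLabel:
    label: str  # inflamed | invasive_margin | desert
    tc_density: float
    im_density: float
    tc_im_ratio: float  # nan when IM density is 0
    thresholds: LandscapeThresholds


def classify_landscape(
    tc_combined: float,
    im_combined: float,
    thresholds: LandscapeThresholds | None = None,
) -> LandscapeLabel:
    """Classify a tumor from combined TC and IM mean densities.

    The rule is total over the non-negative quadrant.  When TC < tc_high and
    IM >= im_high the ratio clause is mathematically redundant
    (TC/IM < tc_high/im_high < ratio_cut) but is still evaluated and recorded.
    """
    t = thresholds or LandscapeThresholds()
    if not (math.isfinite(tc_combined) and math.isfinite(im_combined)):
        raise ValueError("densities must be finite")
    if tc_combined < 0 or im_combined < 0:
        raise ValueError("densities must be non-negative")
    ratio = tc_combined / im_combined if im_combined > 0 else math.nan
    if tc_combined >= t.tc_high:
        label = "inflamed"
    elif im_combined >= t.im_high and not math.isnan(ratio) and ratio < t.ratio_cut:
        label = "invasive_margin"
    else:
        label = "desert"
    return LandscapeLabel(label, float(tc_combined), float(im_combined), ratio, t)


@dataclass(frozen=True)
class PDL1Score:
    """Combined positive score on the x100 clinical scale (or raw fraction)."""

    cps: float  # nan when not evaluable
    evaluable: bool
    n_tumor_cells: int
    tumor_percent: float  # % PD-L1+ of tumor cells (nan if no tumor cells)
    scale: str = "clinical"

    @property
    def cps_ge1(self) -> bool:
        cut = 1.0 if self.scale == "clinical" else 0.01
        return self.evaluable and self.cps >= cut

    @property
    def cps_ge10(self) -> bool:
        cut = 10.0 if self.scale == "clinical" else 0.10
        return self.evaluable and self.cps >= cut


def combined_positive_score(
    n_pdl1_tumor: int,
    n_pdl1_immune: int,
    n_tumor: int,
    scale: str = "clinical",
    min_tumor_cells: int = 100,
) -> PDL1Score:
    """CPS = (PD-L1+ tumor + PD-L1+ immune) / tumor cells, x100 by default.

    Not evaluable (cps = nan) below ``min_tumor_cells`` vital tumor cells or
    when ``n_tumor`` is zero; ``scale="raw"`` skips the x100 convention.
    """
    if min(n_pdl1_tumor, n_pdl1_immune, n_tumor) < 0:
        raise ValueError("counts must be non-negative")
    if n_pdl1_tumor > n_tumor:
        raise ValueError("PD-L1+ tumor cells cannot exceed total tumor cells")
    if scale not in ("clinical", "raw"):
        raise ValueError("scale must be 'clinical' or 'raw'")
    factor = 100.0 if scale == "clinical" else 1.0
    if n_tumor == 0:
        return PDL1Score(math.nan, False, 0, math.nan, scale)
    cps = factor * (n_pdl1_tumor + n_pdl1_immune) / n_tumor
    pct = 100.0 * n_pdl1_tumor / n_tumor
    evaluable = n_tumor >= min_tumor_cells
    return PDL1Score(cps if evaluable else math.nan, evaluable, int(n_tumor), pct, scale)


DEFAULT_PDL1_BINS: tuple[float, ...] = (0.0, 1.0, 5.0, 10.0)


def taic_pdl1_category(
    percent_positive_taics: float, bins: Sequence[float] = DEFAULT_PDL1_BINS
) -> str:
    """Ordinal PD-L1 category of immune cells from their percent positivity.

    Default left-closed bins: 0, 1-4, 5-9, >=10 (configurable).
    """
    p = float(percent_positive_taics)
    if not 0.0 <= p <= 100.0:
        raise ValueError("percent must be in [0, 100]")
    edges = sorted(bins)
    labels = []
    for i, lo in enumerate(edges):
        if i + 1 < len(edges):
            hi = edges[i + 1]
            labels.append(
                f"{lo:g}" if hi - lo <= 1 else f"{lo:g}-{hi - 1:g}"
            )
        else:
            labels.append(f">={lo:g}")
    idx = 0
    for i, lo in enumerate(edges):
        if p >= lo:
            idx = i
    return labels[idx]


def percent_positive(
    cells: pd.DataFrame,
    positive_col: str = "pdl1",
    compartment: str | None = None,
    phenotype: str | None = None,
) -> float:
    """Percent positive cells in a compartment (nan when empty)."""
    sub = cells
    if compartment is not None:
        sub = sub[sub["compartment"] == compartment]
    if phenotype is not None:
        sub = sub[sub["phenotype"] == phenotype]
    if len(sub) == 0:
        return math.nan
    return 100.0 * float(sub[positive_col].mean())


@dataclass
class PatientRecord:
    """Matched biopsy/resection metrics with outcome data.

    ``trg`` is the Mandard tumor-regression grade (1 = complete regression,
    5 = no regression); resection-based metrics are not evaluable at TRG 1
    because no vital tumor remains.
    """

    patient_id: str
    trg: int
    os_months: float
    event: bool
    cps_biopsy: PDL1Score | None = None
    cps_resection: PDL1Score | None = None
    landscape: LandscapeLabel | None = None
    biopsy_metrics: object | None = None
    resection_metrics: object | None = None
    biopsy: object | None = None
    resection: object | None = None
    truth_pattern: str | None = None
    truth_combined_density: float | None = None
    resection_evaluable: bool = True
    seeds: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.trg not in (1, 2, 3, 4, 5):
            raise ValueError("TRG must be in 1..5")
        if self.os_months < 0:
            raise ValueError("os_months must be >= 0")

    @property
    def trg_low(self) -> bool:
        """Good histopathological response (Mandard 1-3)."""
        return self.trg <= 3
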