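"""Brightfield image processing: stain deconvolution, thresholded cell
detection, epithelium segmentation, image alignment, and resolution of
multi-marker detections into single cells.

Color deconvolution follows the optical-density formulation: per pixel,
``OD = -log(transmittance)`` and the per-chromogen amounts are the
least-squares solution of ``OD = M a`` where the columns of ``M`` are the
unit stain vectors.  At most three chromogens can be unmixed per pass (OD
space is three-dimensional); the triplex immune stain and the
pan-cytokeratin stain are processed as separate images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage import filters, measure, morphology

_EPS_TRANSMITTANCE = 1e-6


@dataclass(frozen=True)
class StainVectors:
    """Unit RGB optical-density vectors per chromogen.

    Defaults are standard published hematoxylin/DAB vectors plus plausible
    vectors for the green, red and yellow chromogens; all are calibration
    data and overridable per assay.
    """

    vectors: dict[str, np.ndarray]

    @staticmethod
    def defaults() -> "StainVectors":
        raw = {
            "hematoxylin": (0.650, 0.704, 0.286),
            "dab": (0.268, 0.570, 0.776),
            "vina_green": (0.620, 0.150, 0.770),
            "vulcan_red": (0.180, 0.820, 0.543),
            "stay_yellow": (0.100, 0.210, 0.973),
        }
        return StainVectors(
            {k: np.asarray(v, dtype=float) / np.linalg.norm(v) for k, v in raw.items()}
        )

    def __post_init__(self):
        for name, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (3,):
                raise ValueError(f"stain vector {name!r} must have 3 components")
            if not math.isclose(float(np.linalg.norm(v)), 1.0, abs_tol=1e-6):
                raise ValueError(f"stain vector {name!r} must have unit norm")

    def matrix(self, chromogens: list[str]) -> np.ndarray:
        """3 x k stain matrix for the named chromogens (checked independent)."""
        M = np.stack([self.vectors[c] for c in chromogens], axis=1)
        if np.linalg.matrix_rank(M, tol=1e-8) < M.shape[1]:
            raise ValueError("stain vectors are linearly dependent")
        return M


@dataclass
class ChromogenImage:
    """RGB transmittance raster in [0, 1] with resolution and channel map."""

    rgb: np.ndarray  # (H, W, 3) float
    um_per_px: float
    channel_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.um_per_px <= 0:
            raise ValueError("resolution must be positive")
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be (H, W, 3)")

    def total_od(self) -> np.ndarray:
        return -np.log(np.clip(self.rgb, _EPS_TRANSMITTANCE, 1.0)).sum(axis=2)


def deconvolve(
    image: ChromogenImage,
    stains: StainVectors | None = None,
    chromogens: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Unmix an RGB image into per-chromogen optical-density amount maps.

    Amounts are the least-squares solution against the stain matrix, clipped
    at zero.  Raises for more than three simultaneous chromogens or a
    singular stain matrix.
    """
    stains = stains or StainVectors.defaults()
    if chromogens is None:
        chromogens = sorted(set(image.channel_map.values()))
    if len(chromogens) == 0:
        raise ValueError("no chromogens to unmix")
    if len(chromogens) > 3:
        raise ValueError(
            "at most 3 chromogens per deconvolution pass; unmix the triplex "
            "and the pan-cytokeratin image separately"
        )
    M = stains.matrix(chromogens)
    od = -np.log(np.clip(image.rgb, _EPS_TRANSMITTANCE, 1.0))
    h, w, _ = od.shape
    amounts, *_ = np.linalg.lstsq(M, od.reshape(-1, 3).T, rcond=None)
    amounts = np.clip(amounts, 0.0, None)
    return {c: amounts[i].reshape(h, w) for i, c in enumerate(chromogens)}


@dataclass
class ThresholdResult:
    mask: np.ndarray
    threshold: float  # nan when the input was constant
    method: str
    constant: bool  # warning flag: threshold undefined on a constant map


_THRESHOLD_METHODS = {
    "otsu": filters.threshold_otsu,
    "mean": filters.threshold_mean,
    "triangle": filters.threshold_triangle,
    "yen": filters.threshold_yen,
    "li": filters.threshold_li,
}


def auto_threshold(od_map: np.ndarray, method: str = "otsu") -> ThresholdResult:
    """Histogram auto-threshold of an OD map; foreground is ``od >= t``.

    A constant map has no defined threshold: an empty mask is returned with
    the ``constant`` warning flag set.
    """
    od_map = np.asarray(od_map, dtype=float)
    if not np.isfinite(od_map).all():
        raise ValueError("OD map must be finite")
    if method not in _THRESHOLD_METHODS:
        raise ValueError(f"unknown threshold method {method!r}")
    if od_map.min() == od_map.max():
        return ThresholdResult(np.zeros_like(od_map, dtype=bool), math.nan, method, True)
    t = float(_THRESHOLD_METHODS[method](od_map))
    return ThresholdResult(od_map >= t, t, method, False)


def detect_cells(
    mask: np.ndarray,
    min_area_um2: float,
    max_area_um2: float,
    um_per_px: float,
) -> pd.DataFrame:
    """Centroids (um) of 8-connected components with area in [min, max] um^2."""
    if min_area_um2 > max_area_um2:
        raise ValueError("min_area must be <= max_area")
    px_area = um_per_px * um_per_px
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    rows = []
    for rp in measure.regionprops(labels):
        area_um2 = rp.area * px_area
        if min_area_um2 <= area_um2 <= max_area_um2:
            r, c = rp.centroid
            rows.append(
                {
                    "x_um": (c + 0.5) * um_per_px,
                    "y_um": (r + 0.5) * um_per_px,
                    "area_um2": area_um2,
                }
            )
    return pd.DataFrame(rows, columns=["x_um", "y_um", "area_um2"])


def segment_epithelium(
    panck_od_map: np.ndarray,
    um_per_px: float,
    smoothing_um: float = 20.0,
    method: str = "otsu",
    max_hole_area_um2: float = 2000.0,
) -> np.ndarray:
    """Epithelium mask: Gaussian-smoothed OD, auto-thresholded, holes filled.

    A constant map falls back to ``od > 0`` (all-zero -> empty mask,
    uniformly stained -> full mask).
    """
    od = np.asarray(panck_od_map, dtype=float)
    sm = ndimage.gaussian_filter(od, sigma=smoothing_um / um_per_px)
    res = auto_threshold(sm, method=method)
    mask = (sm > 0) if res.constant else res.mask
    hole_px = int(max_hole_area_um2 / (um_per_px * um_per_px))
    if hole_px > 0 and mask.any():
        mask = morphology.remove_small_holes(mask, max_size=hole_px)
    return mask


def detect_positive_cells(
    od_map: np.ndarray,
    um_per_px: float,
    min_area_um2: float = 10.0,
    max_area_um2: float = 500.0,
    smoothing_um: float = 2.0,
    method: str = "otsu",
) -> pd.DataFrame:
    """Positive-cell detection recipe: smooth, auto-threshold, detect.

    Light Gaussian smoothing (default 2 um, about half a nucleus radius)
    suppresses pixel noise before the histogram threshold; pass
    ``smoothing_um=0`` to threshold the raw map.
    """
    od = np.asarray(od_map, dtype=float)
    if smoothing_um > 0:
        od = ndimage.gaussian_filter(od, sigma=smoothing_um / um_per_px)
    res = auto_threshold(od, method=method)
    if res.constant:
        return pd.DataFrame(columns=["x_um", "y_um", "area_um2"])
    return detect_cells(res.mask, min_area_um2, max_area_um2, um_per_px)


class AlignmentError(RuntimeError):
    """Raised when image registration is unreliable (low correlation)."""


def align_images(
    fixed: ChromogenImage,
    moving: ChromogenImage,
    max_shift_um: float,
    min_correlation: float = 0.1,
) -> tuple[float, float]:
    """Integer-pixel translation (dx, dy in um) aligning `moving` onto `fixed`.

    The shift maximizes the cross-correlation of the zero-meaned total-OD
    images over a +-max_shift window; the normalized correlation at the best
    shift must exceed ``min_correlation`` or an :class:`AlignmentError` is
    raised.  Returned values are the translation to *apply* to the moving
    image (content shifted by +t in the moving image yields a result of -t).
    """
    if not math.isclose(fixed.um_per_px, moving.um_per_px, rel_tol=1e-9):
        raise ValueError("images must share a resolution")
    f = fixed.total_od()
    m = moving.total_od()
    if f.shape != m.shape:
        raise ValueError("images must share a shape")
    wpx = int(round(max_shift_um / fixed.um_per_px))
    if wpx >= min(f.shape) // 2:
        raise ValueError("search window exceeds image size")
    fz = f - f.mean()
    mz = m - m.mean()
    # full cross-correlation; C[k] corresponds to displacement d = k - (N - 1)
    cc = signal.fftconvolve(mz, fz[::-1, ::-1], mode="full")
    cy, cx = f.shape[0] - 1, f.shape[1] - 1
    window = cc[cy - wpx : cy + wpx + 1, cx - wpx : cx + wpx + 1]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    ty, tx = iy - wpx, ix - wpx  # moving[i] ~ fixed[i - t]

    # normalized correlation over the overlap at the best shift
    H, W = f.shape
    msl = mz[max(0, ty) : H + min(0, ty), max(0, tx) : W + min(0, tx)]
    fsl = fz[max(0, -ty) : H + min(0, -ty), max(0, -tx) : W + min(0, -tx)]
    denom = float(np.linalg.norm(fsl) * np.linalg.norm(msl))
    ncc = float((fsl * msl).sum() / denom) if denom > 0 else 0.0
    if ncc < min_correlation:
        raise AlignmentError(f"normalized correlation {ncc:.3f} below floor")
    return (-tx * fixed.um_per_px, -ty * fixed.um_per_px)


def resolve_multimarker(
    detections: dict[str, pd.DataFrame],
    merge_radius_um: float,
    immune_markers: tuple[str, ...] = ("CD8", "FOXP3", "PD1"),
) -> pd.DataFrame:
    """Group nearby immune detections into cells; flag multi-positives.

    Detections of the immune markers within ``merge_radius_um`` are merged by
    single-linkage into one cell at the group centroid.  Cells matched to two
    or more distinct immune markers are flagged ``multipositive`` (excluded
    from density analyses downstream).  Tumor (and any non-immune) detections
    are never merged with immune detections.
    """
    if merge_radius_um < 0:
        raise ValueError("merge_radius must be >= 0")
    from scipy.spatial import cKDTree

    priority = {m: i for i, m in enumerate(immune_markers)}
    pts, marker_of = [], []
    for marker, df in detections.items():
        if marker not in priority or len(df) == 0:
            continue
        for x, y in zip(df["x_um"].to_numpy(), df["y_um"].to_numpy()):
            pts.append((float(x), float(y)))
            marker_of.append(marker)

    rows = []
    if pts:
        coords = np.asarray(pts)
        parent = list(range(len(pts)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        tree = cKDTree(coords)
        for i, j in tree.query_pairs(r=merge_radius_um):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        groups: dict[int, list[int]] = {}
        for i in range(len(pts)):
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            markers = {marker_of[i] for i in members}
            lead = min(markers, key=priority.__getitem__)
            rows.append(
                {
                    "x_um": float(coords[members, 0].mean()),
                    "y_um": float(coords[members, 1].mean()),
                    "phenotype": lead,
                    "pdl1": False,
                    "multipositive": len(markers) >= 2,
                }
            )

    for marker, df in detections.items():
        if marker in priority:
            continue
        for x, y in zip(df["x_um"].to_numpy(), df["y_um"].to_numpy()):
            rows.append(
                {
                    "x_um": float(x),
                    "y_um": float(y),
                    "phenotype": marker,
                    "pdl1": False,
                    "multipositive": False,
                }
            )
    return pd.DataFrame(
        rows, columns=["x_um", "y_um", "phenotype", "pdl1", "multipositive"]
    )
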