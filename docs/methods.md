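# Methods

## The measurement model

The package quantifies tumor-associated immune cells (TAICs) — CD8+,
FOXP3+ and PD-1+ cells — on whole tissue sections the way tile-based
digital-pathology workflows do. The section is covered by a grid of square
tiles (default area 2 mm², read literally as *area*, so side √2 mm; a
2-mm-side preset is a one-line config change). All metrics treat the tile as
the unit of observation: a per-tile density is count / compartment area, and
the reported mean density is the unweighted mean over tiles contributing
that compartment. A pooled alternative (total count / total area) is
available behind `tile_average=False`; the two differ when compartment
areas vary strongly across tiles.

Three compartments partition the tissue: **tumor epithelium**
(pan-cytokeratin+ pixels), **tumor stroma** (non-epithelial tissue inside
tumor-containing tiles) and **non-tumor stroma** (tiles with no epithelium).
Only single-positive immune cells enter density computations; detections
matched to two or more immune markers within the merge radius (default
5 µm, single-linkage) are flagged multipositive and excluded.

### Tumor center vs invasive margin

The original workflow classified tiles manually. The automated stand-in
defines the tumor region as the morphological closing of the epithelium
mask with a disk (default radius 800 µm), fills enclosed holes (interior
stroma belongs to the tumor), and calls a tumor-containing tile **IM** when
it intersects the band within `im_band_um` (default 500 µm) of the region
boundary, **TC** otherwise. The closing radius must exceed the typical gap
between epithelial nests at the tumor edge — with 30% epithelial fill at a
150 µm nest scale, gaps up to ~0.8 mm occur — otherwise the reconstructed
region is fragmented, every tile touches a boundary, and no TC tile exists.
The slide edge counts as boundary, so a section fully covered by tumor has
an IM ring at its rim. All radii and bands are configuration values echoed
into every output manifest.

### Landscape classification

From the combined (CD8 + FOXP3 + PD-1) mean per-tile TAIC densities of the
TC and IM tiles, with thresholds in cells/mm²:

* inflamed: ρ_TC ≥ 75;
* invasive_margin: ρ_TC < 75 and ρ_IM ≥ 400 and ρ_TC/ρ_IM < 0.5;
* desert: everything else.

Thresholds are closed (≥), and the rule is total over the non-negative
quadrant. When ρ_TC < 75 and ρ_IM ≥ 400 the ratio clause is mathematically
redundant (ρ_TC/ρ_IM < 75/400 < 0.5) but is still evaluated and recorded.
When a sample has no IM tiles the ratio is flagged undefined rather than
infinite; a sample with no TC tiles contributes ρ_TC = 0.

### PD-L1 scoring

CPS = 100 · (PD-L1+ tumor cells + PD-L1+ immune cells) / tumor cells. The
×100 convention is the standard clinical scale — the CPS ≥ 1 and CPS ≥ 10
operating points only make sense on it — and a raw-fraction mode exists for
sensitivity analysis. Specimens with fewer than 100 vital tumor cells are
not evaluable, which also covers resections with complete regression
(Mandard TRG 1): those contribute no landscape, CPS or multiplex metrics.
PD-L1 on immune cells is additionally binned ordinally (default 0, 1–4,
5–9, ≥10 percent; configurable), and generic percent-positive scoring per
compartment covers MHC-style markers.

## Image analysis

Brightfield chromogen images follow the Beer–Lambert model: transmitted
RGB = exp(−Σ aᵢ·vᵢ) with unit optical-density stain vectors vᵢ.
Deconvolution takes OD = −log T per pixel and solves the least-squares
system against the stain matrix (at most three chromogens per pass — OD
space is three-dimensional — so the CD8/FOXP3/PD-1 triplex and the
pan-cytokeratin image are unmixed separately), clipping amounts at zero.
Shipped default vectors are standard published hematoxylin/DAB values plus
plausible vectors for the green, red and yellow chromogens; vectors are
calibration data and fully overridable.

Positive-cell detection thresholds an OD map by a histogram method (default
Otsu; mean/triangle/yen/li selectable) and reports centroids of 8-connected
components with area inside [min, max] µm². The recommended recipe smooths
the OD map with a 2 µm Gaussian first; at a noise SD of 0.02 on the
transmittance scale this recovers isolated cells exactly, and the
round trip degrades once noise approaches the blob contrast. A constant map
has no defined threshold and yields an empty mask with a warning flag.
Epithelium segmentation smooths (default 20 µm), thresholds, and fills
holes below a configurable area; on noise-free rendered inputs it overlaps
the generating mask with Jaccard > 0.99. Alignment of restained sections is
integer-pixel translation maximizing the cross-correlation of zero-meaned
total-OD images, with a normalized-correlation floor guarding against
uncorrelated pairs; sub-pixel refinement is deliberately out of scope since
restained physical sections deform negligibly.

## The synthetic-tissue generator

The generator emulates the *statistical* structure the analysis assumes,
not histological appearance. A sample is a fully tissue-covered slide
(default 8×8 mm at 2 µm/px) holding a disc-shaped tumor (radius 3 mm).
Epithelium is smoothed-noise blobs (scale 150 µm) occupying 30% of the
disc; tumor cells fill the blobs at 1000 cells/mm². Immune cells are an
inhomogeneous Poisson process, piecewise-constant over three regions —
tumor interior, a margin band extending 700 µm to each side of the disc
boundary, and outside — with combined intensities per pattern
(interior, margin, outside, cells/mm²):

| pattern | interior | margin | outside |
|---|---|---|---|
| inflamed | 300 | 300 | 20 |
| invasive_margin | 10 | 800 | 20 |
| desert | 10 | 20 | 5 |

split CD8:FOXP3:PD1 = 0.5:0.25:0.25. The margin half-width (700 µm, within
the ≤1 mm definitions of the invasive margin common in the field) is set so
that a margin-restricted tumor *measures* ≥ 400 cells/mm² on straddling
2 mm² IM tiles (intensity × band coverage ≈ 800 × 0.6); a narrower band
would generate a pattern that contradicts its own class definition.
Biopsies are unions of random square crops (default four 1.5 mm fragments
centred in the tumor) re-composed side by side; cells and mask pixels
inside each crop are conserved.

Cohorts draw a pattern per patient (default mix 56/18/26% inflamed /
invasive-margin / desert), jitter per-patient intensities by a mean-one
log-normal (σ = 0.4), and couple outcomes to the standardized combined
biopsy density z: Mandard TRG from a proportional-odds model with slope
`trg_effect` (default 1.0 toward better response) plus a centred CPS ≥ 1
term (`cps_effect`, default 1.5); overall survival exponential with median
36 months at z = 0 and log hazard ratio −0.3 per SD; independent
exponential censoring calibrated to the target censoring fraction (default
0.3). PD-L1 expression is a mixture — 80% of patients express none — so
CPS ≥ 1 prevalence lands near 20%. Per-patient streams derive from
(master seed, patient index), making every draw reproducible and
insertion-order independent.

What the generator does **not** model: spatial clustering of immune cells
beyond region means (the Poisson choice is a modelling convenience), nuclear
texture, stain artifacts, cell shape, touching-cell occlusion, or multiple
tumor foci. Passing tests therefore demonstrate that the pipeline recovers
the parameters of this generative model, not that it is robust to every
property of real slides.

## Statistics

The 2×2 odds ratio uses the (exposure no/yes × outcome reference/event)
orientation, OR = (d/c)/(b/a) — identical to the exponentiated univariate
logistic coefficient — with a Wald CI on the log scale (z = Φ⁻¹(0.975));
zero cells give OR exactly 0 or ∞ with the affected CI bound undefined, and
no continuity correction is applied. Fisher's exact test sums
hypergeometric probabilities ≤ the observed table's in exact `Fraction`
arithmetic (standard two-sided convention, not mid-p; the printed p-value
this package reproduces as 0.011 rounds to the published 0.01 at two
decimals). The trend test is the Mantel–Haenszel linear-by-linear statistic
M² = (N−1)r² on default scores 1..k, referred to χ²(1). Rank tests use the
exact null distribution up to a combined n of 20 without ties and the
midrank normal approximation otherwise; Kruskal–Wallis pairwise
comparisons are Benjamini–Hochberg adjusted within the family — no
study-wide multiplicity correction is applied anywhere else. Survival uses
the product-limit estimator with median defined as the earliest time
survival reaches 0.5 (undefined when the curve never does) and the
(multivariate) log-rank test. Multivariable logistic and Cox modelling is
intentionally not re-implemented; the per-patient table the pipeline emits
is ready for `statsmodels`/`lifelines`.

## Numerical and design choices

* Coordinates are µm, origin top-left, y down; masks default to 2 µm/px.
  Tests and the reproduction script run the generator at 8 µm/px (and
  detection examples at 2–4 µm/px) to keep mask morphology cheap; tile
  metrics are unchanged at that scale because every area and density is
  computed in physical units.
* Tiles with under 10% tissue are dropped to avoid unstable density
  denominators — except when that would drop every tile (a biopsy fragment
  smaller than one tile still yields one tile).
* Deconvolution clips transmittance at 10⁻⁶ before the log; the noise-free
  render→deconvolve round trip is exact to 10⁻⁶.
* Connected components are 8-connected; multi-marker merging is
  single-linkage; both recorded in output metadata.
* Determinism: identical inputs and seeds give bit-identical outputs; every
  output carries a manifest with the configuration hash.

## Known limitations

* The TC/IM band automation is an explicit stand-in for manual tile
  classification; its closing radius and band width are honest free
  parameters, defaulted as above and echoed in outputs.
* Published cohort-level magnitudes (e.g. the 56% inflamed fraction, median
  survival splits) are not reproducible from first principles without the
  study's slides; the synthetic reproduction reports them under the
  generator's own conditions. In particular the end-to-end inflamed
  fraction runs a few points below the nominal 56% mix because landscape is
  only evaluable in resections with residual tumor, and the outcome model
  makes densely infiltrated tumors respond best — the evaluable subset is
  depleted of inflamed cases.
* Watershed splitting of touching nuclei, stain-vector estimation from
  images, and spatial-interaction statistics are out of scope.
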