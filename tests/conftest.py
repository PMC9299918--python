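import numpy as np
import pandas as pd
import pytest

from immunoscape import TissueGeometry, TissueSample, generate_tissue

#: coarse raster used throughout the suite to keep mask operations cheap;
#: densities and tile metrics are resolution-invariant at this scale
COARSE = TissueGeometry(um_per_px=8.0)


@pytest.fixture(scope="session")
def inflamed_sample():
    return generate_tissue("inflamed", geometry=COARSE, seed=11)


@pytest.fixture(scope="session")
def desert_sample():
    return generate_tissue("desert", geometry=COARSE, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_sample(cells: pd.DataFrame, shape=(200, 200), um_per_px=8.0,
                epithelium=None, tissue=None, sample_id="synthetic"):
    """Hand-built sample for targeted geometry tests."""
    tissue_mask = np.ones(shape, bool) if tissue is None else tissue
    epi = np.zeros(shape, bool) if epithelium is None else epithelium
    return TissueSample(
        sample_id=sample_id,
        sample_type="resection",
        cells=cells,
        epithelium_mask=epi,
        tissue_mask=tissue_mask,
        um_per_px=um_per_px,
    )


def cell_frame(xs, ys, phenotypes, pdl1=False, multipositive=False):
    n = len(xs)
    return pd.DataFrame(
        {
            "x_um": np.asarray(xs, float),
            "y_um": np.asarray(ys, float),
            "phenotype": phenotypes if not isinstance(phenotypes, str)
            else [phenotypes] * n,
            "pdl1": np.broadcast_to(pdl1, n).copy(),
            "multipositive": np.broadcast_to(multipositive, n).copy(),
        }
    )
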