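import numpy as np
import pandas as pd
import pytest

from stabscale import CommunityTensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_tensor():
    """2 subplots x 3 years, one species per subplot, cover == biomass.

    Series (1,2,3) and (1,3,2): hand-computable moments
    (v = [[1, 0.5], [0.5, 1]], mu = (2, 2)).
    """
    cover = np.zeros((2, 2, 3))
    cover[0, 0] = [1, 2, 3]
    cover[1, 1] = [1, 3, 2]
    biomass = np.array([[1, 2, 3], [1, 3, 2]], dtype=float)
    return CommunityTensor(
        site_id="toy",
        treatment="Control",
        duration_years=3,
        species_list=("A", "B"),
        subplots=(1, 2),
        cover=cover,
        biomass=biomass,
    )


@pytest.fixture
def cover_biomass_frames():
    """A tiny complete 1-site, 2-subplot, 3-year long-format dataset."""
    rows = []
    for block in (1, 2):
        for year in (1, 2, 3):
            rows.append(("s1", block, "Control", year, "Poa pratensis",
                         10.0 + block + year))
            if block == 1:
                rows.append(("s1", block, "Control", year, "Festuca rubra",
                             5.0 + year))
    cover = pd.DataFrame(
        rows,
        columns=["site_code", "block", "trt", "year_trt", "Taxon", "max_cover"],
    )
    brows = [("s1", b, "Control", y, 100.0 + 10 * b + y)
             for b in (1, 2) for y in (1, 2, 3)]
    biomass = pd.DataFrame(
        brows,
        columns=["site_code", "block", "trt", "year_trt", "live_mass"],
    )
    return cover, biomass
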