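import numpy as np
import pandas as pd
import pytest

from fragfit.data_model import Study


@pytest.fixture
def tiny_study() -> Study:
    """Two fragmented landscapes' worth of hand-checkable data.

    Three fragmented landscapes (needed by the candidate catalogue) with
    two sites each plus one paired control, two specialists and one
    generalist.
    """
    landscapes = pd.DataFrame(
        {
            "landscape_id": ["L50", "L30", "L10", "C50"],
            "forest_cover_percent": [50.0, 30.0, 10.0, 100.0],
            "is_control": [False, False, False, True],
            "paired_with": ["", "", "", "L50"],
        }
    )
    sites = pd.DataFrame(
        {
            "site_id": ["s1", "s2", "s3", "s4", "s5", "s6", "k1"],
            "landscape_id": ["L50", "L50", "L30", "L30", "L10", "L10", "C50"],
            "patch_area_ha": [10.0, 100.0, 5.0, 50.0, 2.0, 20.0, np.nan],
            "is_control": [False] * 6 + [True],
        }
    )
    species = pd.DataFrame(
        {
            "species_id": ["spA", "spB", "genA"],
            "guild": ["specialist", "specialist", "generalist"],
        }
    )
    captures = pd.DataFrame(
        {
            "site_id": ["s1", "s1", "s1", "s2", "s3", "k1", "k1"],
            "species_id": ["spA", "spA", "spB", "spA", "genA", "spA", "spB"],
            "year": [1, 2, 2, 1, 1, 1, 2],
            "individuals": [2, 1, 3, 4, 5, 1, 2],
        }
    )
    return Study(landscapes=landscapes, sites=sites, species=species, captures=captures)
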