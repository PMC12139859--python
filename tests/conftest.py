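import numpy as np
import pandas as pd
import pytest

import chromaging as cg


@pytest.fixture
def small_layout():
    return cg.GenomeLayout(("chr1", "chr2"), (2_000_000, 1_000_000))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def study_config():
    """Default-scale synthetic study with two planted DAR clusters."""
    return cg.SimConfig(
        seed=0,
        planted_hotspots=(
            cg.HotspotSpec("chr1", 5_000_000, 500_000, 50),
            cg.HotspotSpec("chr3", 12_000_000, 500_000, 50),
        ),
    )


def make_cells(rows):
    """Cell table from (cell_type, age, sex, region, replicate) tuples."""
    df = pd.DataFrame(rows, columns=["cell_type", "age", "sex", "region", "replicate"])
    df.insert(0, "cell_id", [f"c{i}" for i in range(len(df))])
    return df
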