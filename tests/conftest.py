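import numpy as np
import pandas as pd
import pytest

from spatial_ime.io import AnalysisConfig, LineageSet


@pytest.fixture
def ab_lineages() -> LineageSet:
    return LineageSet(names=("A", "B"), cancer="A")


@pytest.fixture
def abc_lineages() -> LineageSet:
    return LineageSet(names=("A", "B", "C"), cancer="A")


@pytest.fixture
def fast_config() -> AnalysisConfig:
    return AnalysisConfig(n_perm=2000, score_cutoff=1000, rng_seed=0)


def make_cells(xy, lineage, image_id="img1"):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:04d}" for i in range(len(xy))],
            "image_id": image_id,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "lineage": list(lineage),
        }
    )


@pytest.fixture
def toy_cells():
    return make_cells([(0, 0), (5, 0), (20, 20)], ["A", "B", "A"])
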