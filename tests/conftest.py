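import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from imbalmicro.phylo import PhyloTree
from imbalmicro.synthetic import SyntheticConfig, generate_dataset, generate_tree
from imbalmicro.tables import SampleMetadata, TaxaTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def count_table():
    data = pd.DataFrame(
        [[2, 3, 5, 0], [10, 0, 30, 60], [1200, 400, 0, 400]],
        index=["s1", "s2", "s3"],
        columns=["tA", "tB", "tC", "tD"],
    )
    return TaxaTable(data, normalized=False)


@pytest.fixture
def metadata():
    df = pd.DataFrame(
        {
            "smoking_status": ["never", "former", "current"],
            "sex": ["female", "male", "female"],
            "age_group": ["60-69", "50-59", "70-79"],
            "ethnicity": ["European", "European", "Non-European"],
            "study": ["S1", "S1", "S2"],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return SampleMetadata(df)


@pytest.fixture
def small_tree(rng):
    return generate_tree(8, rng)


@pytest.fixture
def cherry_tree():
    return PhyloTree.from_newick_string("(taxon_0001:0.1,taxon_0002:0.2);")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort with planted signal, shared across tests."""
    cfg = SyntheticConfig(
        n_minority=30, n_majority=180, n_taxa=40, effect_taxa=6, seed=7
    )
    return generate_dataset(cfg)
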