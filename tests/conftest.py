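import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import gutnetdys as g

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_table():
    """3 samples × 2 taxa with total 15."""
    return g.ActivityTable(
        pd.DataFrame(
            [[5, 0], [1, 2], [0, 7]],
            index=["s1", "s2", "s3"],
            columns=["t1", "t2"],
        )
    )


@pytest.fixture
def small_meta():
    rows = []
    for i, (section, dose) in enumerate(
        [("midgut", 0.0), ("midgut", 0.1), ("ileum", 0.0)]
    ):
        rows.append(
            {
                "sample_id": f"s{i + 1}",
                "cage": f"c{i + 1}",
                "gut_section": section,
                "dose_ppb": dose,
                "replicate": 1,
                "timepoint_day": 7,
            }
        )
    return g.types.validate_metadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_run():
    """One deterministic full synthetic study shared across tests."""
    cfg = g.SynthConfig(seed=11)
    data = g.generate_all(cfg)
    data["config"] = cfg
    data["genus_table"] = g.aggregate_genus(data["activity"], data["lineages"])
    return data


def make_lineage(**ranks):
    return g.Lineage.from_ranks(ranks)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
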