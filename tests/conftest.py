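import numpy as np
import pandas as pd
import pytest

from phyllocom.datamodel import CountTable, SampleMeta


@pytest.fixture
def toy_table() -> CountTable:
    return CountTable(
        pd.DataFrame(
            [[5, 0], [1, 2], [0, 0]],
            index=["s1", "s2", "s3"],
            columns=["otu1", "otu2"],
        )
    )


def make_meta(
    sample_ids,
    host="R_acris",
    organ="leaf",
    time_point=1,
    time_series=1,
    control="none",
    pooled=False,
) -> SampleMeta:
    """Build a SampleMeta where each argument is a scalar or per-sample list."""
    n = len(sample_ids)

    def expand(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * n

    return SampleMeta(
        pd.DataFrame(
            dict(
                host=expand(host), organ=expand(organ),
                time_point=expand(time_point), time_series=expand(time_series),
                control=expand(control), pooled=expand(pooled),
            ),
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )


@pytest.fixture
def small_community():
    """A small but fully structured synthetic dataset shared across tests."""
    from phyllocom.synthetic import SyntheticDesign, simulate_community

    design = SyntheticDesign(
        n_otus=80, samples_per_cell=2, time_points_per_series=(4, 3),
        missing_cells=(), depth_range=(2000, 12000), rng_seed=7,
    )
    return simulate_community(design)
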