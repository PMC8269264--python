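import numpy as np
import pandas as pd
import pytest

import bariomics as bm


@pytest.fixture(scope="session")
def toy():
    """The committed 12-subject, 8-taxon toy fixture."""
    return bm.load_toy_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared by read-only tests."""
    spec = bm.CohortSpec(seed=7, n_obese=40, n_lean=30)
    return bm.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_zscored(small_cohort):
    table, meta, truth = small_cohort
    return bm.normalize_pipeline(table), meta, truth


def make_table(values, feature_ids=None, sample_ids=None, taxonomy=None,
               stage="raw"):
    """Build a FeatureTable from a plain array with generic taxonomy."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    feature_ids = feature_ids or [f"F{j}" for j in range(p)]
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    if taxonomy is None:
        taxonomy = {f: f"k__Bacteria; p__P{j}; c__C{j}; o__O{j}; f__Fam{j}; g__G{j}"
                    for j, f in enumerate(feature_ids)}
    data = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    return bm.FeatureTable(data=data, taxonomy=taxonomy, stage=stage)
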