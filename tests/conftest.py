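import numpy as np
import pandas as pd
import pytest

from bioreg import AnalysisConfig, apply_curation_filters
from bioreg.community import AbundanceTable
from bioreg.synthetic import make_study_fixture


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig(rng_seed=1)


@pytest.fixture(scope="session")
def bundle():
    """The 4-region, ~400-sample, 160-species strong-separation fixture."""
    return make_study_fixture(seed=1)


@pytest.fixture(scope="session")
def curated(bundle, cfg):
    table, _ = apply_curation_filters(bundle.table, bundle.taxon_metadata, cfg)
    return table


@pytest.fixture(scope="session")
def full_cube(curated, cfg):
    """Scores for the complete 9-approach × K=2..20 grid on the fixture."""
    from bioreg.selection import build_score_cube
    return build_score_cube(curated, cfg)


def random_table(rng, n=8, s=6, sparsity=0.4, state="raw"):
    """Small random abundance table; every row/column has at least one presence."""
    while True:
        vals = np.where(rng.random((n, s)) > sparsity,
                        rng.integers(1, 50, (n, s)).astype(float), 0.0)
        if (vals.sum(axis=1) > 0).all() and (vals.sum(axis=0) > 0).all():
            break
    df = pd.DataFrame(vals, index=[f"s{i}" for i in range(n)],
                      columns=[f"t{j}" for j in range(s)])
    return AbundanceTable(df, transform_state=state)


def random_labels(rng, n, k):
    """Random labels 1..k guaranteed to use all k clusters."""
    while True:
        labels = rng.integers(1, k + 1, n)
        if len(np.unique(labels)) == k:
            return labels
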