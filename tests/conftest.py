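import logging

import pandas as pd
import pytest

from placmine.simulate import SimConfig, simulate_omics_cohort
from placmine.stats import run_differential

logging.getLogger("placmine").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across tests (omics layers only)."""
    return simulate_omics_cohort(SimConfig(seed=11), with_corpus=False)


@pytest.fixture(scope="session")
def default_screens(default_study):
    groups = default_study.phenotypes["group"]
    meth = run_differential(default_study.methylome, groups, layer="methylation")
    expr = run_differential(default_study.transcriptome, groups, layer="expression")
    return meth, expr


@pytest.fixture(scope="session")
def small_corpus():
    """A small fast 3-topic corpus for text-mining unit tests."""
    cfg = SimConfig(
        seed=5,
        n_genes=36,
        n_topics=3,
        vocab_size=160,
        topic_pool_size=30,
        abstracts_per_gene_range=(8, 12),
        abstract_length=10,
    )
    from placmine.simulate import simulate_annotation_corpus

    return simulate_annotation_corpus(cfg)


@pytest.fixture(scope="session")
def feature_matrix(default_study, default_screens):
    meth, expr = default_screens
    from placmine.model import select_features

    selected = select_features(meth, expr)
    return pd.concat([default_study.methylome, default_study.transcriptome]).loc[selected]
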