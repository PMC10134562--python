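"""Shared fixtures: synthetic bundles generated once per session."""

import pytest
from dataclasses import replace

from labbgc.synthetic_data import (
    EASY,
    gen_bgc_features,
    gen_community,
    gen_gene_models,
    gen_metagenome_counts,
    gen_precursors,
)


@pytest.fixture(scope="session")
def easy_cfg():
    return replace(EASY, seed=11)


@pytest.fixture(scope="session")
def feature_bundle(easy_cfg):
    return gen_bgc_features(easy_cfg)


@pytest.fixture(scope="session")
def count_bundle(easy_cfg, feature_bundle):
    features, _ = feature_bundle
    models = gen_gene_models(easy_cfg, features.bgc_ids)
    table, truth = gen_metagenome_counts(easy_cfg, models)
    return models, table, truth


@pytest.fixture(scope="session")
def precursor_bundle(easy_cfg):
    return gen_precursors(easy_cfg)


@pytest.fixture(scope="session")
def community_bundle(easy_cfg):
    return gen_community(easy_cfg)
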