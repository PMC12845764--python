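"""Shared fixtures.

The expensive artifacts — the desk-scale fixture dataset, the fitted
reference classifier, and the five seeded end-to-end pipeline runs —
are session-scoped so every test file shares one copy.
"""

from __future__ import annotations

import numpy as np
import pytest

from mcwavegan.classify import LdaSvmClassifier
from mcwavegan.features import desk_feature_config
from mcwavegan.fixtures import FixtureConfig, gen_dataset
from mcwavegan.pipeline import run_desk_experiment
from mcwavegan.preprocess import desk_preprocess_config

PIPELINE_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def desk_data():
    """20 ten-second fixture clips per class -> ~200 desk-rate segments/class."""
    return gen_dataset(
        n_per_class=20, cfg=FixtureConfig(), seed=11,
        preprocess=desk_preprocess_config(),
    )


@pytest.fixture(scope="session")
def desk_split(desk_data):
    """Deterministic 80/20 split of the desk dataset."""
    rng = np.random.default_rng(7)
    idx = rng.permutation(len(desk_data))
    n_train = int(0.8 * len(idx))
    return desk_data.subset(idx[:n_train]), desk_data.subset(idx[n_train:])


@pytest.fixture(scope="session")
def desk_model(desk_split):
    """Reference MFCC->LDA->SVM classifier fitted on the training split."""
    train, _ = desk_split
    model = LdaSvmClassifier(rate=train.rate, feature_config=desk_feature_config())
    return model.fit_segments(train)


@pytest.fixture(scope="session")
def pipeline_runs():
    """Five seeded end-to-end desk pipeline runs (fixtures -> GAN ->
    generate -> β-sweep refinement -> classify -> divergences).

    This is the workhorse behind the scaled-down directional analyses;
    it dominates the suite's runtime, so every consumer shares it.
    """
    return [
        run_desk_experiment(seed=s, max_iters=2_000_000) for s in PIPELINE_SEEDS
    ]
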