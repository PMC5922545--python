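"""Shared fixtures: small seeded simulator scenes and a trained classifier.

Session-scoped where construction is expensive; everything is seeded so the
suite is deterministic end to end.
"""

import numpy as np
import pytest

import phenotray as pt
from phenotray import training


@pytest.fixture(scope="session")
def small_params() -> pt.SimParams:
    """A 4 x 8 tray with 48-px pots: fast to render, full marker layout."""
    return pt.SimParams(pot_w_px=48, pot_h_px=48, seed=7,
                        growth=pt.GrowthParams(a0_px=20, amax_px=500,
                                               rate=0.3))


@pytest.fixture(scope="session")
def small_geom() -> pt.TrayGeometry:
    return pt.TrayGeometry(pot_w=48, pot_h=48)


@pytest.fixture(scope="session")
def gt_pairs() -> list:
    """Twenty pot-scale ground-truth pairs at deployment size (224 px)."""
    params = pt.SimParams(seed=11)
    return pt.generate_groundtruth_pack(params, 20, seed=11)


@pytest.fixture(scope="session")
def feature_set(gt_pairs) -> training.LabeledFeatureSet:
    return training.assemble(gt_pairs)


@pytest.fixture(scope="session")
def rf_model(feature_set) -> training.SuperpixelClassifier:
    return training.train(feature_set, algorithm="rf", seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
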