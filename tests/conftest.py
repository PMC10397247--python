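import warnings

import pytest

from ccortho import ccgen, synth
from ccortho.scoring import FeatureConfig, ScoringModel


@pytest.fixture(autouse=True)
def _quiet_rank_warnings():
    # the invariant-d default library makes dd/intercept collinear by
    # design; the fit warns once per call, which would swamp test output
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="design matrix is rank-deficient"
        )
        yield


@pytest.fixture(scope="session")
def default_spec():
    return ccgen.LibrarySpec()


@pytest.fixture(scope="session")
def full_library(default_spec):
    """The complete default four-heptad a/e/g library (4,096 coils)."""
    return ccgen.enumerate_library(default_spec)


@pytest.fixture(scope="session")
def small_library():
    """A 1-heptad, 8-coil library for hand-checkable cases."""
    return ccgen.enumerate_library(ccgen.LibrarySpec(n_heptads=1))


@pytest.fixture()
def toy_model():
    """Hand-specified weights over the I/L/E/K alphabet, no intercept."""
    return ScoringModel(
        pair_weights={
            "aa_core": {"II": 2.0},
            "dd": {"LL": 0.5},
            "ge": {"EK": 1.0},
        },
        intercept=0.0,
        config=FeatureConfig(use_nterm=False, use_shifting=False),
        missing_weight="zero",
    )


@pytest.fixture(scope="session")
def true_model():
    return synth.make_true_model(11)


@pytest.fixture(scope="session")
def random_library():
    return synth.random_coils(30, seed=12)
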