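import numpy as np
import pytest

from emomeg import CohortSpec, EffectSpec, assemble_feature_sets, iter_epochs


@pytest.fixture(scope="session")
def tiny_spec():
    """A fast cohort: full 33 subjects but few channels/trials."""
    return CohortSpec(
        n_channels=8, trials_per_category=(6, 8), seed=11
    )


@pytest.fixture(scope="session")
def toy_spec():
    """A very small cohort for shape/convention checks."""
    return CohortSpec(
        n_controls=3,
        n_patients=3,
        n_channels=4,
        trials_per_category=(5, 6),
        seed=7,
    )


@pytest.fixture(scope="session")
def toy_feature_sets(toy_spec):
    return assemble_feature_sets(iter_epochs(toy_spec))


@pytest.fixture(scope="session")
def labeled_noise_design():
    """Pure-noise design at study geometry (17 controls / 16 patients)."""
    rng = np.random.default_rng(5)
    X = rng.normal(size=(33, 12))
    y = np.concatenate([np.ones(17), np.zeros(16)])
    return X, y
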