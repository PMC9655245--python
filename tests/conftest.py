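import numpy as np
import pytest

from dualscreen import ise, synth


@pytest.fixture(scope="session")
def canonical_dataset():
    """Two-class descriptor table: 200+200 molecules, 20 descriptors of
    which 3 informative at 3-sd class separation."""
    table, labels, informative = synth.make_classification_dataset(
        synth.ClassificationSpec(seed=0)
    )
    return table, labels, informative


@pytest.fixture(scope="session")
def trained_model(canonical_dataset):
    """Filter-ensemble model trained once on the canonical dataset."""
    table, labels, _ = canonical_dataset
    return ise.train_model(table, labels, ise.ISEConfig(seed=0))


@pytest.fixture(scope="session")
def fast_config():
    """Reduced search settings for tests that train many models."""
    return ise.ISEConfig(
        seed=0, n_iterations=8, filters_per_iteration=100, mcc_min=-1.0
    )
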