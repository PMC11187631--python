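import numpy as np
import pytest

import hergsuite as hs


@pytest.fixture(scope="session")
def planted():
    """Noise-free planted-signal fixture: (table, truth, FixtureSpec)."""
    spec = hs.FixtureSpec(n_compounds=120, noise_sd=0.0, seed=3)
    library = hs.make_library(spec.n_compounds, seed=3)
    table, truth = hs.plant_activity(library, spec)
    return table, truth, spec


@pytest.fixture(scope="session")
def curated_binary(planted):
    table, _, _ = planted
    return hs.curate_dataset(table, hs.CurationConfig(task="binary"))


@pytest.fixture(scope="session")
def fps_binary(curated_binary):
    return hs.featurize_dataset(curated_binary, hs.FingerprintSpec())


@pytest.fixture(scope="session")
def trained_binary(curated_binary, fps_binary):
    """A small gradient-boosted binary model on the planted fixture."""
    y = np.array(curated_binary.labels)
    train_idx, test_idx = hs.stratified_split(y, seed=42)
    spec = hs.ModelSpec(task="binary", algorithm="gbt_light",
                        hyperparameters={"max_iter": 60})
    bundle = hs.train_model(spec, fps_binary.bits[train_idx], y[train_idx])
    return bundle, train_idx, test_idx, y
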