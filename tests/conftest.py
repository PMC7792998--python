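import numpy as np
import pytest

import cdinvert as ci
import cdinvert.neural_inverter as ni


@pytest.fixture(scope="session")
def grid32():
    return ci.GridSpec(32, 32)


@pytest.fixture(scope="session")
def config32(grid32):
    return ci.SimulatorConfig(grid=grid32)


@pytest.fixture(scope="session")
def particle32(config32):
    obj, prov = ci.sample_random_particle(config32, seed=11)
    return obj, prov


@pytest.fixture(scope="session")
def sample32(particle32):
    obj, prov = particle32
    return ci.make_training_sample(obj, prov)


@pytest.fixture(scope="session")
def particle64():
    cfg = ci.SimulatorConfig(grid=ci.GridSpec(64, 64))
    obj, prov = ci.sample_random_particle(cfg, seed=11)
    return obj, prov


@pytest.fixture(scope="session")
def solvable64(particle64):
    """A 64x64 retrieval instance that is exactly consistent with its support:
    the projection is truncated to the support mask and re-diffracted, so the
    truncated projection is a true solution satisfying both constraints."""
    obj, _ = particle64
    full, _ = ci.project(obj, "z")
    mask = np.abs(full) >= 1e-3 * np.abs(full).max()
    truth = np.where(mask, full, 0.0)
    pattern = ci.diffract_2d(truth)
    return pattern, ci.Support(mask=mask), truth


@pytest.fixture(scope="session")
def corpus32():
    """Small simulated corpus shared by NNS / evaluation tests."""
    cfg = ci.SimulatorConfig(grid=ci.GridSpec(32, 32))
    return ci.simulate_dataset(cfg, 80, seed=123)


@pytest.fixture(scope="session")
def trained_setup():
    """Scaled-down training study shared by the learned-inversion tests.

    Corpus and model sizes are chosen so the full study (simulation,
    training, evaluation) runs in a few minutes on one CPU while the
    qualitative orderings of the full-scale study are preserved.
    """
    cfg = ci.SimulatorConfig(grid=ci.GridSpec(64, 64))
    dataset = ci.simulate_dataset(cfg, 900, seed=2024)
    model_cfg = ni.ModelConfig(input_size=64, base_channels=12, depth=3)
    trained = ni.train(
        dataset, model_cfg, ni.LossWeights(1.0, 1.0, 1.0),
        epochs=18, batch_size=32, lr=1e-3, seed=7,
    )
    return dataset, trained
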