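import numpy as np
import pytest

import scenesim as ss


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_prototypes():
    """Six well-scaled prototypes on 30 voxels for fast simulator tests."""
    return ss.generate_prototypes(n_voxels=30, separation=0.5, rng_seed=42)


@pytest.fixture(scope="session")
def separable_prototypes():
    """Hugely separated prototypes: decoding must be perfect at low noise."""
    return ss.generate_prototypes(n_voxels=30, separation=50.0, rng_seed=7)


def make_config(prototypes, sigma_good=0.1, sigma_noise=0.1, **kw):
    return ss.SimulationConfig(
        prototypes=prototypes,
        variance_spec=ss.ExemplarVarianceSpec.with_double_variance(sigma_good),
        sigma_noise=sigma_noise,
        **kw,
    )


@pytest.fixture()
def block_runs_factory(small_prototypes):
    """Factory producing n block runs with controllable noise levels."""

    def factory(n_runs=6, sigma_good=0.1, sigma_noise=0.1, seed=0, prototypes=None,
                condition="good"):
        protos = prototypes if prototypes is not None else small_prototypes
        config = make_config(protos, sigma_good, sigma_noise)
        rng = np.random.default_rng(seed)
        design = ss.BlockDesign()
        runs = []
        for r in range(n_runs):
            order = list(rng.permutation(ss.CATEGORY_NAMES))
            runs.append(ss.simulate_block_run(design, config, order, rng, condition, run_id=r))
        return runs

    return factory
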