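import numpy as np
import pytest
from hypothesis import settings

from bymtrends import (
    IndicatorDataset,
    IndicatorObservation,
    ModelSpec,
    SamplerSettings,
    fit,
    make_lattice,
)
from bymtrends.simulate import TruthSpec, generate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# Small sampler for property tests that need a valid posterior, not precision.
TINY_SAMPLER = dict(iterations=900, burnin=300, thin=1, chains=2)


@pytest.fixture(scope="session")
def lattice33():
    return make_lattice(3, 3)


@pytest.fixture(scope="session")
def small_dataset(lattice33):
    truth = TruthSpec(alpha0=-0.3, beta0=float(np.log(1.2)), sd_u=0.4, sd_v=0.1, sd_delta=0.15,
                      n_range=(30, 60), seed=42)
    dataset, synth = generate(lattice33, truth)
    return dataset, synth


@pytest.fixture(scope="session")
def small_fit_interaction(lattice33, small_dataset):
    dataset, _ = small_dataset
    spec = ModelSpec(family="binary", include_interaction=True,
                     sampler=SamplerSettings(seed=7, **TINY_SAMPLER))
    return fit(dataset, lattice33, spec)


@pytest.fixture(scope="session")
def small_fit_nointeraction(lattice33, small_dataset):
    dataset, _ = small_dataset
    spec = ModelSpec(family="binary", include_interaction=False,
                     sampler=SamplerSettings(seed=8, **TINY_SAMPLER))
    return fit(dataset, lattice33, spec)


def tiny_spec(**kw):
    sampler = {**TINY_SAMPLER, **kw.pop("sampler_kwargs", {})}
    seed = kw.pop("seed", 1)
    return ModelSpec(sampler=SamplerSettings(seed=seed, **sampler), **{"family": "binary", **kw})


@pytest.fixture
def one_block_dataset():
    obs = [IndicatorObservation("X", 6, 10, 20)]
    return IndicatorDataset("onecell", "binary", obs, rounds=(6,))
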