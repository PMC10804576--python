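import numpy as np
import pandas as pd
import pytest

from tasa import fixtures as fx
from tasa.core import BetaMatrix


@pytest.fixture(scope="session")
def small_cfg() -> fx.FixtureConfig:
    return fx.FixtureConfig(n_probes=600, batch_sizes=(12, 8, 6), seed=11)


@pytest.fixture(scope="session")
def manifest(small_cfg):
    return fx.make_manifest(small_cfg)


@pytest.fixture(scope="session")
def planted_regions(small_cfg, manifest):
    return fx.make_truth_regions(small_cfg, manifest)


@pytest.fixture(scope="session")
def source_beta(small_cfg, manifest, planted_regions):
    return fx.make_source_beta(small_cfg, manifest, planted_regions)


@pytest.fixture(scope="session")
def reference_pair(small_cfg, manifest, planted_regions):
    return fx.make_reference_pair(small_cfg, manifest, planted_regions)


def random_beta(n_probes: int, n_samples: int, seed: int = 0) -> BetaMatrix:
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.01, 0.99, size=(n_probes, n_samples))
    return BetaMatrix(
        pd.DataFrame(
            vals,
            index=[f"cg{i:05d}" for i in range(n_probes)],
            columns=[f"S{j:03d}" for j in range(n_samples)],
        )
    )
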