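import numpy as np
import pytest

from modenet.core import pairwise_distance, rank_edges
from modenet.pipeline import build_synthetic_suite
from modenet.synth import SynthConfig


@pytest.fixture(scope="session")
def small_cfg():
    return SynthConfig(n_regions=40, n_modes=3, seed=11)


@pytest.fixture(scope="session")
def small_suite(small_cfg):
    """40-region, 3-mode synthetic study shared across tests."""
    return build_synthetic_suite(small_cfg)


@pytest.fixture(scope="session")
def mid_suite():
    """80-region, 4-mode suite for statistics that need more edges."""
    return build_synthetic_suite(SynthConfig(n_regions=80, n_modes=4, seed=7))


@pytest.fixture(scope="session")
def small_tables(small_suite):
    return [rank_edges(m, small_suite["distance"]) for m in small_suite["modes"]]
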