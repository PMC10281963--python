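"""Shared fixtures: tiny synthetic targets, decoys and featurized graphs."""

import numpy as np
import pytest

from ifaceqe.gat_network import GATConfig, GATParams
from ifaceqe.pipeline import featurize_model
from ifaceqe.synthetic_data import (SyntheticSpec, generate_decoys,
                                    generate_native, target_msas)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Small bundle: fast to generate, still spans the DockQ spectrum."""
    return SyntheticSpec(n_targets=4, decoys_per_target=14,
                         chain_length_range=(30, 40), msa_depth=12, seed=42)


@pytest.fixture(scope="session")
def native(small_spec):
    return generate_native(small_spec, 0)


@pytest.fixture(scope="session")
def decoy_set(small_spec, native):
    return generate_decoys(native, small_spec, 0)


@pytest.fixture(scope="session")
def msas(small_spec, native):
    return target_msas(native, small_spec, 0)


@pytest.fixture(scope="session")
def labeled_graph(native, decoy_set, msas):
    """Featurized, labeled graph of a mid-quality decoy."""
    _, decoy, _ = decoy_set.decoys[3]
    return featurize_model(decoy, msas=msas, native=native)


@pytest.fixture(scope="session")
def params() -> GATParams:
    return GATParams(GATConfig(random_seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_rigid(rng):
    """A random proper rotation and translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t
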