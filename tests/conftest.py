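import numpy as np
import pytest

from denopot.backbones import BackboneConfig, init_model
from denopot.synthetic import (
    SyntheticDatasetSpec,
    generate_benchmark_suite,
    minimize,
    random_chain_forcefield,
)
from denopot.systems import AtomicConformation


@pytest.fixture(scope="session")
def small_dataset():
    """4 molecules × 40 labeled conformations; session-cached."""
    spec = SyntheticDatasetSpec(
        n_molecules=4, conformations_per_molecule=40, seed=11
    )
    return generate_benchmark_suite(spec)


@pytest.fixture(scope="session")
def chain_system():
    """A minimized 7-atom chain force field and its minimum geometry."""
    rng = np.random.default_rng(3)
    ff, x0 = random_chain_forcefield(7, rng)
    res = minimize(ff, x0, tol=1e-5, max_steps=5000)
    assert res.converged
    return ff, res.coordinates


@pytest.fixture
def random_conformations():
    rng = np.random.default_rng(42)
    confs = []
    for k in range(3):
        n = int(rng.integers(4, 9))
        confs.append(
            AtomicConformation(
                atomic_numbers=rng.choice([1, 6, 7, 8], size=n),
                coordinates=rng.uniform(-3, 3, size=(n, 3)),
                molecule_id=f"m{k}",
                conformation_id="0",
            )
        )
    return confs


@pytest.fixture(params=["invariant_conv", "equivariant_egnn"])
def small_model(request):
    cfg = BackboneConfig(
        architecture=request.param,
        feature_dim=16,
        num_layers=2,
        num_radial_basis=8,
    )
    return init_model(cfg, seed=7)
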