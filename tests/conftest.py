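import pytest

from ecmito import generate_toy_model, build_full_toy
from ecmito.pmf import PMFSpec, add_pmf_sink, apply_pmf_coupling, close_non_oxphos_pmf_drains

SEED = 1


@pytest.fixture(scope="session")
def toy():
    """Base toy network (no PMF coupling, no enzyme constraints)."""
    model, manifest = generate_toy_model(SEED)
    return model, manifest


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def coupled_model(toy_model):
    """PMF-coupled toy network with the sink present."""
    return add_pmf_sink(apply_pmf_coupling(toy_model, PMFSpec()))


@pytest.fixture(scope="session")
def oxphos_model(coupled_model):
    """Coupled network with all non-OXPHOS PMF drains closed."""
    return close_non_oxphos_pmf_drains(coupled_model)


@pytest.fixture(scope="session")
def full_model():
    """Fully layered fixture: PMF + import + cofactors + enzyme pool."""
    model, _ = build_full_toy(SEED)
    return model


@pytest.fixture(scope="session")
def exchange_dataset(full_model):
    from ecmito import generate_exchange_dataset

    return generate_exchange_dataset(
        full_model, gaec=18.0, sigma=0.53, mus=[0.1, 0.2, 0.3, 0.36, 0.4], seed=SEED
    )
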