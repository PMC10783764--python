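import pytest

from antisdscan.rrna_tail import CoreAnnotation, TailRecord, locate_core
from antisdscan.thermo import CANONICAL_TAIL, load_energy_model


@pytest.fixture(scope="session")
def model():
    return load_energy_model()


@pytest.fixture(scope="session")
def canonical_tail():
    return TailRecord("ecoli_like", CANONICAL_TAIL)


@pytest.fixture(scope="session")
def canonical_core(canonical_tail):
    return locate_core(canonical_tail)


@pytest.fixture(scope="session")
def small_organism(model):
    """A verified 250-gene synthetic organism shared by several tests."""
    from antisdscan.simulate import SyntheticSpec, generate_organism

    return generate_organism(
        SyntheticSpec(n_genes=250, sd_fraction=0.6, seed=42), model=model
    )


@pytest.fixture(scope="session")
def small_calls(small_organism, model):
    from antisdscan.scan import scan_organism

    return scan_organism(
        small_organism.utrs, small_organism.tail, small_organism.core, model
    )
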