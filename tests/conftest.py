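import pytest

from persistome import WorldSpec, generate_world


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world (24 genomes, 120 families) with truth."""
    return generate_world(WorldSpec(seed=11))


@pytest.fixture(scope="session")
def clean_world():
    """A noise-free world: no dropout, no plasmids — planted structure exact."""
    spec = WorldSpec(
        seed=7,
        presence_prob=1.0,
        background_presence_prob=0.0,
        n_background_families=0,
        plasmid_fraction=0.0,
    )
    return generate_world(spec)


@pytest.fixture(scope="session")
def tiny_world():
    """A small world for I/O round-trips and CLI smoke tests."""
    spec = WorldSpec(
        seed=3,
        n_genomes=6,
        n_families=30,
        n_background_families=5,
        genome_size_bp=600_000,
        emit_sequences=True,
        seq_len=60,
    )
    return generate_world(spec)
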