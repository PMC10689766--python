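import pytest

from vipseq.simulate import ProphageSpec, SimulationConfig, simulate


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A compact two-prophage lysogen that runs in well under a second."""
    defaults = dict(
        seed=seed,
        genome_len_bp=200_000,
        genome_gc=0.50,
        prophages=(
            ProphageSpec(length_bp=20_000, gc=0.45, titre=1e7, insertion_pos=60_000),
            ProphageSpec(length_bp=40_000, gc=0.55, titre=5e6, insertion_pos=150_000),
        ),
        background_read_fraction=0.02,
        total_read_pairs=20_000,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_truth():
    """One fully simulated dataset shared across read-only tests."""
    return simulate(small_config(seed=7))
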