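import pytest

from breakins.simulate import (
    SimulationConfig,
    render_reads,
    simulate_events,
    simulate_reference,
)


@pytest.fixture(scope="session")
def mock():
    """Deterministic mock reference bundle shared across the suite."""
    return simulate_reference(7)


@pytest.fixture(scope="session")
def amplicon(mock):
    return mock.design.amplicon_seq(mock.genome)


@pytest.fixture(scope="session")
def clean_dataset(mock):
    """Error-free study conditions: no sequencing error, hopping, or spike-ins."""
    config = SimulationConfig(
        seed=11, n_products=300,
        per_base_error_rate=0.0, index_hop_rate=0.0, phix_fraction=0.0,
    )
    events = simulate_events(mock, config)
    pairs = render_reads(events, mock, config)
    return config, events, pairs


@pytest.fixture(scope="session")
def clean_result(mock, clean_dataset):
    from breakins.pipeline import run_from_objects

    _, events, pairs = clean_dataset
    result = run_from_objects(pairs, mock.genome, mock.design, mock.decoy_seq)
    return events, result
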