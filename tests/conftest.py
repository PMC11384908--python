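import pytest

from lymphpump.io import ProtocolSpec, Segment
from lymphpump.synthetic import SimulationConfig


@pytest.fixture
def baseline_protocol():
    """A single 5 min baseline segment starting at t = 0."""
    return ProtocolSpec([Segment("baseline", "baseline", 0.0, 300.0)])


@pytest.fixture
def drug_protocol():
    """Baseline (10 min) → drug (20 min) → rescue (10 min)."""
    return ProtocolSpec(
        [
            Segment("baseline", "baseline", 0.0, 600.0),
            Segment("drug", "drug", 600.0, 1800.0, drug="rotenone 100 nM"),
            Segment("rescue", "rescue", 1800.0, 2400.0, drug="GLIB 1 uM"),
        ]
    )


@pytest.fixture
def clean_config():
    """Noise-free regular twitching at 10 cpm over 5 min."""
    return SimulationConfig(
        duration_s=300.0, freq_cpm=10.0, amplitude_um=40.0,
        noise_sd_um=0.0, seed=0,
    )
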