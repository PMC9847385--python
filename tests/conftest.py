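import numpy as np
import pytest

from virin.config import PipelineConfig
from virin.io_formats import FastaRecord
from virin.simulator import SimulationConfig, simulate_sample


def random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture(scope="session")
def panel() -> list[FastaRecord]:
    """Two small synthetic panel viruses."""
    rng = np.random.default_rng(1234)
    return [
        FastaRecord("virusA", "synthetic", random_seq(rng, 400)),
        FastaRecord("virusB", "synthetic", random_seq(rng, 350)),
    ]


@pytest.fixture(scope="session")
def clean_sim():
    """Small error-free simulated sample: 2 insertions, 40 kb host, 25x."""
    cfg = SimulationConfig(
        seed=7, host_length=40_000, n_insertions=2, virus_length=3_000,
        coverage=25, error_rate=0.0, min_spacing=5_000,
    )
    sample, prov = simulate_sample(cfg)
    return sample, prov


@pytest.fixture(scope="session")
def desk_config() -> PipelineConfig:
    """Pipeline config with the per-virus read cutoff scaled down to desk scale."""
    cfg = PipelineConfig()
    cfg.screen.min_virus_reads = 20
    return cfg
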