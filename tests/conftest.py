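"""Shared fixtures: small synthetic studies generated once per session."""

import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from avian_itv import synth  # noqa: E402


@pytest.fixture(scope="session")
def small_dataset() -> synth.SyntheticDataset:
    """5 species x 6 stations, seed 42: the default small study."""
    cfg = synth.SimConfig(n_species=5, n_locations_per_species=6, seed=42)
    return synth.simulate_captures(cfg)


@pytest.fixture(scope="session")
def medium_dataset() -> synth.SyntheticDataset:
    """5 species x 10 stations x ~30 individuals, seed 42."""
    cfg = synth.SimConfig(
        n_species=5,
        n_locations_per_species=10,
        n_individuals_range=(30, 30),
        seed=42,
    )
    return synth.simulate_captures(cfg)
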