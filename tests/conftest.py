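import numpy as np
import pytest

from msocc import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small paper-like simulated dataset (40 sites, 4 seasons)."""
    return simulate(SimulationConfig(n_sites=40, n_seasons=4, seed=11))


@pytest.fixture()
def toy_file(tmp_path):
    """Three sites, one season of four surveys, one missing survey."""
    text = (
        "# site s1v1 s1v2 s1v3 s1v4 zone ruggedness crops scrub distance\n"
        "A 0 1 0 . 1 10.0 100.0 5.0 250.0\n"
        "B 2 2 2 2 0 20.0 200.0 6.0 500.0\n"
        "C 0 0 0 0 1 30.0 300.0 7.0 750.0\n"
    )
    path = tmp_path / "toy.txt"
    path.write_text(text)
    return path
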