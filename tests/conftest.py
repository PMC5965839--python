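import numpy as np
import pandas as pd
import pytest

from vegnet.plot_data import (DEFAULT_COVER_SCALE, DEFAULT_ENV_ATTRIBUTES, PlotTable)
from vegnet.synthetic import SimulationConfig, sample_ground_truth, simulate_plots


@pytest.fixture(scope="session")
def small_truth():
    """A small ground-truth network with strong effects, shared across tests."""
    cfg = SimulationConfig(n_species=10, n_env=4, n_plots=600,
                           effect_strength=2.0, seed=101)
    return sample_ground_truth(cfg)


@pytest.fixture(scope="session")
def small_table(small_truth):
    return simulate_plots(small_truth, 600, seed=102)


def make_plot_table(n_plots: int = 40, n_species: int = 3, seed: int = 0) -> PlotTable:
    """A hand-built valid plot table with random cover labels."""
    rng = np.random.default_rng(seed)
    labels = DEFAULT_COVER_SCALE.labels
    df = pd.DataFrame({
        "plot_id": [f"p{i}" for i in range(n_plots)],
        "lon": rng.uniform(-9, 3, n_plots),
        "lat": rng.uniform(36, 44, n_plots),
        "Twarm": rng.uniform(15, 30, n_plots),
        "anualP": rng.uniform(300, 1500, n_plots),
        "soil": rng.choice(["siliceous", "calcareous", "mix"], n_plots),
        "orientation": rng.choice(["N", "S", "E", "W"], n_plots),
        "landuse": rng.choice(["forest", "agri", "mix"], n_plots),
        "dom_form": rng.choice(["tree", "shrub", "mix"], n_plots),
    })
    species = [f"sp{i + 1}" for i in range(n_species)]
    for sp in species:
        df[sp] = rng.choice(labels, n_plots)
    return PlotTable(df=df, species=species,
                     env_attributes=list(DEFAULT_ENV_ATTRIBUTES))
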