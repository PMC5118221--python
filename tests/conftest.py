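import numpy as np
import pandas as pd
import pytest

from baystdetect import (
    McmcSettings,
    PriorConfig,
    SimulationConfig,
    build_spatial_graph,
    icar_structure,
    run_mcmc,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def path3_structure():
    g = build_spatial_graph([("A", "B"), ("B", "C")], ["A", "B", "C"])
    return icar_structure(g)


@pytest.fixture(scope="session")
def grid3_graph():
    from baystdetect import grid_graph

    return grid_graph(3, 3)


@pytest.fixture(scope="session")
def small_panel():
    """4x4 grid, 6 time points, moderate counts; no unusual areas."""
    cfg = SimulationConfig(
        grid=(4, 4), n_areas=16, n_times=6, expected_range=(80, 200), seed=42
    )
    panel, truth, graph = simulate_dataset(cfg)
    return panel, truth, graph


@pytest.fixture(scope="session")
def small_fit(small_panel):
    """One short shared MCMC run for tests that only need plausible draws."""
    panel, truth, graph = small_panel
    samples = run_mcmc(
        panel,
        graph,
        PriorConfig(),
        McmcSettings(n_chains=2, n_iter=1500, n_burnin=500, thin=2, seed=9),
    )
    return panel, truth, graph, samples


@pytest.fixture()
def toy_population():
    rows = [
        ("A", "young", "M", 100), ("A", "young", "F", 120),
        ("A", "old", "M", 50), ("A", "old", "F", 80),
        ("B", "young", "M", 200), ("B", "young", "F", 180),
        ("B", "old", "M", 90), ("B", "old", "F", 110),
    ]
    return pd.DataFrame(rows, columns=["area", "age_band", "sex", "count"])
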