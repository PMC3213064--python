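import numpy as np
import pytest

from germpop.panel import GenotypePanel, GeneticMap


def random_panel(n_lines=50, n_markers=100, missing=0.10, seed=0):
    """Random inbred panel ({0,1} dosages) with MCAR missingness."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, n_markers)
    X = (rng.random((n_lines, n_markers)) < p).astype(float)
    if missing:
        X[rng.random(X.shape) < missing] = np.nan
    return GenotypePanel(
        line_ids=[f"l{i}" for i in range(n_lines)],
        marker_ids=[f"m{j}" for j in range(n_markers)],
        dosage=X,
    )


def grid_map(marker_ids, n_groups=2, spacing=5.0):
    """Evenly spaced map cycling marker blocks over n_groups groups."""
    per = int(np.ceil(len(marker_ids) / n_groups))
    groups, pos = [], []
    for j, _ in enumerate(marker_ids):
        groups.append(chr(ord("A") + j // per))
        pos.append((j % per) * spacing)
    return GeneticMap.from_arrays(marker_ids, groups, pos)


@pytest.fixture
def small_panel():
    return random_panel()


@pytest.fixture
def small_map(small_panel):
    return grid_map(small_panel.marker_ids)


@pytest.fixture(scope="session")
def default_scenario_panel():
    """One default-scenario synthetic panel, shared across tests."""
    from germpop.simulate import ScenarioConfig, generate_panel

    return generate_panel(ScenarioConfig(seed=20))
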