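import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def brute_pearson(x, y) -> float:
    """Textbook Pearson r, independent of the library paths under test."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by the slower integration tests."""
    from portrait.simulate import SimConfig, simulate_cohort

    config = SimConfig(
        seed=42,
        n_tumors_per_subtype=6,
        n_cells_per_subtype=2,
        n_genes=120,
        n_marker_genes=20,
        panel_size=40,
        n_protein_genes=12,
        n_proteins=16,
        clone_cell_from_tumor=True,
    )
    return simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160822)
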