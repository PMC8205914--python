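import numpy as np
import pytest

from duosnp import (CohortSpec, SimParams, generate_cohort, simulate_families,
                    synthetic_panel)


@pytest.fixture(scope="session")
def panel200():
    """A 200-marker spaced high-MAF panel with cM positions."""
    return synthetic_panel(n_markers=200, seed=11)


@pytest.fixture(scope="session")
def half_freq_panel():
    """A 160-marker panel with minor-allele frequency exactly 0.5."""
    panel = synthetic_panel(n_markers=160, seed=7)
    df = panel.df.copy()
    df["freq_minor"] = 0.5
    from duosnp import MarkerTable

    return MarkerTable(df)


@pytest.fixture(scope="session")
def family_batch(half_freq_panel):
    """10,000 gene-dropped families at MAF 0.5, independent transmission."""
    return simulate_families(half_freq_panel,
                             SimParams(n_families=10_000, seed=31, linkage_enabled=False))


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic population cohort plus its ground truth."""
    return generate_cohort(CohortSpec(seed=5))


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
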