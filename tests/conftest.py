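import pandas as pd
import pytest
from hypothesis import settings

from tactsupp import DesignSpec, compute_sdt_cells, make_cohort, simulate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """Six-participant paper-like cohort at design-scale trial counts."""
    models = make_cohort(6, preset="paper_like", seed=11)
    return simulate_cohort(models, DesignSpec(), seed=12)


@pytest.fixture(scope="session")
def small_cells(small_cohort) -> pd.DataFrame:
    cells, _ = compute_sdt_cells(small_cohort.trials, seed=13)
    return cells
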