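import numpy as np
import pandas as pd
import pytest

from stratde import CountTable, LibraryInfo, SyntheticSpec, simulate_counts

FOUR_LIBS = {
    "ctrl_A": LibraryInfo("ctrl_A", "A", "control"),
    "diab_A": LibraryInfo("diab_A", "A", "diabetic"),
    "ctrl_B": LibraryInfo("ctrl_B", "B", "control"),
    "diab_B": LibraryInfo("diab_B", "B", "diabetic"),
}


def make_table(counts: dict[str, list[int]], genes: list[str] | None = None) -> CountTable:
    """Build a four-library CountTable from per-column count lists."""
    n = len(next(iter(counts.values())))
    genes = genes or [f"g{i}" for i in range(1, n + 1)]
    df = pd.DataFrame(
        {k: np.asarray(v, dtype=np.int64) for k, v in counts.items()},
        index=pd.Index(genes, name="gene_id"),
    )
    libs = {k: FOUR_LIBS[k] for k in counts}
    return CountTable(df, libs)


def random_table(rng: np.random.Generator, n_genes: int = 1000, scale: float = 50.0) -> CountTable:
    counts = {
        lab: rng.poisson(rng.gamma(1.0, scale, n_genes)).astype(np.int64)
        for lab in FOUR_LIBS
    }
    return make_table(counts)


@pytest.fixture(scope="session")
def default_study():
    """One default-parameter synthetic study, shared across tests."""
    return simulate_counts(SyntheticSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
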