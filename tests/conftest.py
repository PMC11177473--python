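import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import triadhet as th

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_triad():
    """2000-gene triad with default pattern proportions, 3 reps, phi=0.05."""
    return th.simulate_triad(th.TriadSimConfig(n_genes=2000, seed=1))


@pytest.fixture(scope="session")
def small_de(small_triad):
    return th.triad_de(small_triad.counts)


def make_matrix(rows: dict[str, list[int]], genotypes: list[str]):
    """Tiny ExpressionMatrix helper: rows are gene -> counts per sample."""
    sample_ids = [f"s{i}" for i in range(len(genotypes))]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    reps: dict[str, int] = {}
    rep_idx = []
    for g in genotypes:
        reps[g] = reps.get(g, 0) + 1
        rep_idx.append(reps[g])
    design = pd.DataFrame(
        {"genotype": genotypes, "replicate": rep_idx},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return th.ExpressionMatrix(counts, design)


@pytest.fixture
def matrix_factory():
    return make_matrix
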