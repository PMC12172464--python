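import numpy as np
import pandas as pd
import pytest

from microtensor import (
    DataCube,
    FitConfig,
    ParafacModel,
    SampleTable,
    SimSpec,
    build_cube,
    simulate_trilinear,
)


def truth_model(truth: dict) -> ParafacModel:
    """Wrap generator ground-truth loadings as a model for congruence scoring."""
    F = truth["A"].shape[1]
    return ParafacModel(
        A=truth["A"], B=truth["B"], C=truth["C"],
        weights=np.ones(F), n_components=F,
    )


@pytest.fixture
def small_table() -> SampleTable:
    """Complete 2 subjects x 3 features x 2 times count table."""
    rows = [
        {"subject": s, "time": t, "feature": f, "count": c}
        for (s, t, f, c) in [
            ("s1", "t1", "a", 0), ("s1", "t1", "b", 1), ("s1", "t1", "c", 3),
            ("s1", "t2", "a", 2), ("s1", "t2", "b", 0), ("s1", "t2", "c", 5),
            ("s2", "t1", "a", 4), ("s2", "t1", "b", 4), ("s2", "t1", "c", 0),
            ("s2", "t2", "a", 1), ("s2", "t2", "b", 2), ("s2", "t2", "c", 3),
        ]
    ]
    meta = pd.DataFrame({"group": ["g1", "g2"]}, index=["s1", "s2"])
    meta.index.name = "subject"
    return SampleTable(counts=pd.DataFrame(rows), metadata=meta)


@pytest.fixture
def small_cube(small_table) -> DataCube:
    return build_cube(small_table, ["t1", "t2"])


@pytest.fixture
def rank2_cube():
    """Noisy rank-2 cube with its generating loadings."""
    return simulate_trilinear(SimSpec(I=10, J=8, K=6, F=2, noise_sd=0.05, seed=42))


@pytest.fixture
def tight_cfg() -> FitConfig:
    return FitConfig(ctol=1e-10, maxit=2000, seed=0)
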