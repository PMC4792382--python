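"""Shared fixtures.

The expensive end-to-end benchmark pipeline (simulate -> train -> test) is
session-scoped so the acceptance-level tests and the classifier property
tests share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from sweepshape.classifier import SweepShapeClassifier
from sweepshape.experiments import (
    DeskScaleConfig,
    _labeled_from_pools,
    featurize,
    run_reproduction,
)
from sweepshape.simulate import SimulationConfig, build_training_scenarios


def random_haplotype_matrix(
    rng: np.random.Generator, n_max: int = 12, s_max: int = 15
) -> np.ndarray:
    """Random binary matrix whose columns are all segregating."""
    n = rng.integers(2, n_max + 1)
    S = rng.integers(1, s_max + 1)
    cols = []
    for _ in range(S):
        while True:
            c = rng.integers(0, 2, size=n)
            if 0 < c.sum() < n:
                break
        cols.append(c)
    return np.column_stack(cols).astype(np.uint8)


@pytest.fixture(scope="session")
def small_model():
    """A classifier trained on a small equilibrium simulation set.

    Accuracy is incidental; the fixture exists so prediction, serialization
    and scan tests have a genuinely fitted model of the right shape.
    """
    cfg = SimulationConfig(
        demography="equilibrium", alpha_range=(250.0, 2500.0), reps=12, seed=99
    )
    groups = build_training_scenarios(cfg)
    pools = {cls: featurize(sc) for cls, sc in groups.items()}
    train = _labeled_from_pools(pools)
    clf = SweepShapeClassifier(grid="small", folds=3, random_state=0)
    clf.fit(train.X, train.y)
    return clf


@pytest.fixture(scope="session")
def repro():
    """One full desk-scale reproduction run shared by the acceptance tests."""
    return run_reproduction(7, DeskScaleConfig())
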