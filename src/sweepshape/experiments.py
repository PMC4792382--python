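"""Desk-scale reproduction of the classifier's benchmark experiments.

This module wires the whole pipeline together — simulate training scenarios,
build feature vectors, fit classifiers, simulate independent test sets, and
measure ROC AUCs and per-class call fractions — at sizes a single CPU
handles in minutes.  The experimental design mirrors the published
benchmarks: equilibrium training over three selection-strength ranges
(weak alpha ~ U(25, 250), intermediate U(250, 2500), strong U(2500, 25000)),
a pooled classifier trained on their concatenation, distance-from-sweep
profiles, and demographic-misspecification tests in which the
equilibrium-trained classifier is applied to simulations under the African
growth and European two-contraction human models.

The misspecification experiments apply the same equilibrium-trained pooled
classifier to the non-equilibrium test sets, whose standing-variant sweeps
draw f ~ U(2/(2N), 0.2) — a deliberately broader onset-frequency range than
the training design, part of what makes those tasks hard.

Replicate counts are configurable; the defaults (250 per class for
training, 200 test instances per condition, composite test sides of 200)
keep full pipeline runs around a quarter hour on one CPU while leaving
Monte-Carlo noise on AUCs near +/- 0.01-0.03.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import (
    LabeledSet,
    SweepShapeClassifier,
    concat_labeled_sets,
)
from .evaluate import build_composite_test_set, classifier_roc
from .features import build_feature_vector
from .simulate import (
    SimulationConfig,
    SweepScenario,
    build_training_scenarios,
    simulate_region,
)

__all__ = [
    "ALPHA_RANGES",
    "DeskScaleConfig",
    "ReproductionResult",
    "featurize",
    "training_batch",
    "test_pool",
    "run_reproduction",
]

#: the three selection-coefficient ranges of the equilibrium training design
ALPHA_RANGES = {
    "weak": (25.0, 250.0),
    "mid": (250.0, 2500.0),
    "strong": (2500.0, 25_000.0),
}

_MAX_SEED = 2**31 - 1


def _child_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % _MAX_SEED)


def featurize(scenarios: list[SweepScenario]) -> np.ndarray:
    """Simulate each scenario and build its feature vector."""
    return np.array([build_feature_vector(simulate_region(s)) for s in scenarios])


def _labeled_from_pools(pools: dict[str, np.ndarray]) -> LabeledSet:
    X_parts, y_parts = [], []
    for cls, X in pools.items():
        X_parts.append(np.asarray(X))
        y_parts.append(np.full(len(X), cls, dtype=object))
    return LabeledSet(np.concatenate(X_parts), np.concatenate(y_parts))


def training_batch(
    alpha_range: tuple[float, float],
    reps_per_class: int,
    seed: int,
    demography: str = "equilibrium",
    f_range: tuple[float, float] | None = None,
) -> LabeledSet:
    """One balanced five-class training batch for a selection range."""
    cfg = SimulationConfig(
        demography=demography,
        alpha_range=alpha_range,
        f_range=f_range,
        reps=reps_per_class,
        seed=seed,
    )
    groups = build_training_scenarios(cfg)
    X_parts, y_parts = [], []
    for cls, scenarios in groups.items():
        X_parts.append(featurize(scenarios))
        y_parts.append(np.full(len(scenarios), cls, dtype=object))
    return LabeledSet(np.concatenate(X_parts), np.concatenate(y_parts))


def test_pool(
    kind: str,
    n: int,
    seed: int,
    alpha_range: tuple[float, float] | None = None,
    demography: str = "equilibrium",
    f_range: tuple[float, float] | None = None,
    offset: int = 0,
) -> np.ndarray:
    """Feature vectors for n independent test regions of one condition.

    ``kind`` is "hard", "soft" or "neutral"; ``offset`` displaces the sweep
    from the central subwindow (test regions at |offset| >= 1 are linked
    regions; both signs are used alternately).
    """
    cfg = SimulationConfig(
        demography=demography,
        alpha_range=alpha_range,
        f_range=f_range,
        reps=n,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    children = iter(np.random.SeedSequence(seed).spawn(n))
    centre = cfg.n_subwindows // 2
    scenarios = []
    from .simulate import _draw_scenario  # shared prior-draw logic

    for i in range(n):
        if kind == "neutral":
            scenarios.append(_draw_scenario(cfg, "neutral", None, rng, next(children)))
        else:
            j = centre + (offset if i % 2 == 0 else -offset)
            scenarios.append(_draw_scenario(cfg, kind, j, rng, next(children)))
    return featurize(scenarios)


@dataclass
class DeskScaleConfig:
    """Problem sizes for one full reproduction run."""

    reps_per_class: int = 250
    n_test: int = 200
    composite_scale: float = 0.2
    grid: str | dict = "small"
    folds: int = 10


@dataclass
class ReproductionResult:
    """Metrics plus the fitted classifiers and test pools behind them."""

    metrics: dict[str, dict]
    classifiers: dict[str, SweepShapeClassifier] = field(default_factory=dict)
    pools: dict[str, np.ndarray] = field(default_factory=dict)


def run_reproduction(seed: int, cfg: DeskScaleConfig | None = None) -> ReproductionResult:
    """Run the full benchmark suite and return its headline numbers.

    Every quantity is recomputed from scratch: training simulations, grid
    search, independent test simulations, AUCs and call fractions.  All
    randomness derives from ``seed``.
    """
    cfg = cfg or DeskScaleConfig()
    root = np.random.SeedSequence(seed)
    seeds = iter(root.spawn(64))
    R, n_test = cfg.reps_per_class, cfg.n_test

    # -- equilibrium training: three alpha ranges, soft f ~ U(0.05, 0.2) ----
    batches: dict[str, LabeledSet] = {}
    for name, alpha_range in ALPHA_RANGES.items():
        cfg_range = SimulationConfig(
            demography="equilibrium",
            alpha_range=alpha_range,
            reps=R,
            seed=_child_seed(next(seeds)),
        )
        groups = build_training_scenarios(cfg_range)
        batches[name] = _labeled_from_pools(
            {cls: featurize(sc) for cls, sc in groups.items()}
        )

    def fit(train: LabeledSet, seed_: int) -> SweepShapeClassifier:
        clf = SweepShapeClassifier(
            grid=cfg.grid, folds=cfg.folds, random_state=seed_ % _MAX_SEED
        )
        return clf.fit(train.X, train.y)

    clf_mid = fit(batches["mid"], _child_seed(next(seeds)))
    clf_weak = fit(batches["weak"], _child_seed(next(seeds)))
    clf_pooled = fit(concat_labeled_sets(list(batches.values())), _child_seed(next(seeds)))

    # -- independent equilibrium test pools ---------------------------------
    pools = {
        "neutral": test_pool("neutral", n_test, _child_seed(next(seeds))),
        "hard_mid": test_pool("hard", n_test, _child_seed(next(seeds)), ALPHA_RANGES["mid"]),
        "hard_weak": test_pool("hard", n_test, _child_seed(next(seeds)), ALPHA_RANGES["weak"]),
        "soft_mid": test_pool("soft", n_test, _child_seed(next(seeds)), ALPHA_RANGES["mid"]),
        "hard_strong": test_pool(
            "hard", n_test, _child_seed(next(seeds)), ALPHA_RANGES["strong"]
        ),
        "soft_strong": test_pool(
            "soft", n_test, _child_seed(next(seeds)), ALPHA_RANGES["strong"]
        ),
        "hard_mid_offset2": test_pool(
            "hard", n_test, _child_seed(next(seeds)), ALPHA_RANGES["mid"], offset=2
        ),
    }

    def frac(clf, X, classes) -> float:
        pred = clf.predict(X)
        return 100.0 * float(np.mean(np.isin(pred, list(classes))))

    def auc_binary(clf, pos_pool, neg_pool, positive) -> float:
        X = np.concatenate([pos_pool, neg_pool])
        y = np.concatenate([np.ones(len(pos_pool)), np.zeros(len(neg_pool))])
        return classifier_roc(clf, X, y, positive).auc

    metrics: dict[str, dict] = {}

    def record(name, value, n):
        metrics[name] = {"value": float(value), "n": int(n)}

    record(
        "auc_hard_vs_neutral_mid_matched",
        auc_binary(clf_mid, pools["hard_mid"], pools["neutral"], ("hard",)),
        2 * n_test,
    )
    record(
        "auc_hard_vs_neutral_weak_matched",
        auc_binary(clf_weak, pools["hard_weak"], pools["neutral"], ("hard",)),
        2 * n_test,
    )
    record(
        "auc_hard_vs_neutral_weak_pooled_training",
        auc_binary(clf_pooled, pools["hard_weak"], pools["neutral"], ("hard",)),
        2 * n_test,
    )
    record(
        "pct_central_hard_mid_labeled_hard",
        frac(clf_pooled, pools["hard_mid"], ("hard",)),
        n_test,
    )
    record(
        "pct_hard_mid_offset2_labeled_sweep",
        frac(clf_pooled, pools["hard_mid_offset2"], ("hard", "soft")),
        n_test,
    )
    record(
        "pct_central_soft_mid_labeled_soft",
        frac(clf_pooled, pools["soft_mid"], ("soft",)),
        n_test,
    )
    record(
        "pct_central_soft_strong_labeled_soft",
        frac(clf_pooled, pools["soft_strong"], ("soft",)),
        n_test,
    )
    record(
        "pct_central_hard_strong_labeled_hardlinked",
        frac(clf_pooled, pools["hard_strong"], ("hard-linked",)),
        n_test,
    )

    # -- demographic misspecification: equilibrium-trained classifier,
    #    non-equilibrium test simulations ----------------------------------
    side = int(round(1000 * cfg.composite_scale))
    R_comp = side // 2 + 2
    for name, demog, alpha_range in (
        ("african", "african_growth", (5.0e3, 5.0e4)),
        ("european", "european_tennessen", (5.0e3, 5.0e5)),
    ):
        comp_cfg = SimulationConfig(
            demography=demog,
            alpha_range=alpha_range,
            reps=R_comp,
            seed=_child_seed(next(seeds)),
        )
        groups = build_training_scenarios(comp_cfg)
        comp_pools = {cls: featurize(sc) for cls, sc in groups.items()}
        X, y, positive = build_composite_test_set(
            "sweep_vs_unselected",
            comp_pools,
            scale=cfg.composite_scale,
            rng=_child_seed(next(seeds)),
        )
        record(
            f"auc_sweep_vs_unselected_{name}_misspecified",
            classifier_roc(clf_pooled, X, y, positive).auc,
            len(y),
        )
        pools.update({f"{name}_{cls}": fx for cls, fx in comp_pools.items()})

    return ReproductionResult(
        metrics=metrics,
        classifiers={"mid": clf_mid, "weak": clf_weak, "pooled": clf_pooled},
        pools=pools,
    )
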