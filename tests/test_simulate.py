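"""Simulation engine: scenario construction, trajectories, and the
coalescent properties of simulated regions."""

from __future__ import annotations

import numpy as np
import pytest

from sweepshape.demography import equilibrium
from sweepshape.features import partition_subwindows
from sweepshape.simulate import (
    SimulationConfig,
    SweepScenario,
    build_scenario_set,
    build_training_scenarios,
    simulate_region,
    simulate_trajectory,
)
from sweepshape.stats import haplotype_stats, site_stats

EQ = equilibrium(10_000)
THETA, RHO = 550.0, 880.0


def _scenario(true_class="hard", **kw):
    base = dict(
        demography=EQ,
        theta=THETA,
        rho=RHO,
        alpha=2500.0,
        tau=0.0,
        sweep_subwindow=5,
        seed=1,
    )
    base.update(kw)
    return SweepScenario(true_class=true_class, **base)


class TestScenarioValidation:
    def test_neutral_carries_no_sweep_parameters(self):
        with pytest.raises(ValueError, match="neutral"):
            SweepScenario(
                true_class="neutral", demography=EQ, theta=THETA, rho=RHO, alpha=100.0
            )

    def test_sweeps_require_positive_alpha(self):
        with pytest.raises(ValueError, match="alpha"):
            _scenario(alpha=-5.0)

    def test_soft_f_bounds(self):
        with pytest.raises(ValueError, match="f < 1"):
            _scenario("soft", f=1e-6)
        with pytest.raises(ValueError, match="f < 1"):
            _scenario("soft", f=None)
        ok = _scenario("soft", f=0.1)
        assert ok.f == 0.1

    def test_hard_has_no_f(self):
        with pytest.raises(ValueError, match="no standing frequency"):
            _scenario(f=0.1)

    def test_sweep_position_formula(self):
        assert _scenario(sweep_subwindow=5).sweep_position == pytest.approx(11 / 22)
        assert _scenario(
            "hard-linked", sweep_subwindow=0
        ).sweep_position == pytest.approx(1 / 22)

    def test_linked_classes_off_centre(self):
        with pytest.raises(ValueError, match="central"):
            _scenario("hard", sweep_subwindow=3)
        with pytest.raises(ValueError, match="off-centre"):
            _scenario("hard-linked", sweep_subwindow=5)


class TestScenarioSets:
    def test_full_design_counts(self):
        cfg = SimulationConfig(alpha_range=(250, 2500), reps=1, seed=0)
        assert len(build_scenario_set(cfg)) == 23
        cfg = SimulationConfig(alpha_range=(250, 2500), reps=3, seed=0)
        scenarios = build_scenario_set(cfg)
        assert len(scenarios) == 69
        counts = {}
        for s in scenarios:
            counts[s.true_class] = counts.get(s.true_class, 0) + 1
        # 1 central + 10 off-centre positions per sweep type
        assert counts == {
            "hard": 3,
            "hard-linked": 30,
            "soft": 3,
            "soft-linked": 30,
            "neutral": 3,
        }

    def test_alpha_range_must_be_ordered(self):
        with pytest.raises(ValueError, match="alpha_range"):
            SimulationConfig(alpha_range=(100, 100))

    def test_african_alpha_to_s_conversion(self):
        # alpha = 2 N s with the African reference size N = 424,000
        cfg = SimulationConfig(demography="african_growth", alpha_range=(5e3, 5e4), reps=1, seed=0)
        s = cfg.demography.reference_size
        assert 5.0e3 / (2 * s) == pytest.approx(5.9e-3, rel=0.01)

    def test_balanced_training_draw(self):
        cfg = SimulationConfig(alpha_range=(250, 2500), reps=7, seed=3)
        groups = build_training_scenarios(cfg)
        assert {k: len(v) for k, v in groups.items()} == {
            c: 7 for c in ("hard", "hard-linked", "soft", "soft-linked", "neutral")
        }
        assert all(s.sweep_subwindow == 5 for s in groups["hard"])
        assert all(s.sweep_subwindow != 5 for s in groups["hard-linked"])
        # scenario seeds are recorded for reproducibility
        assert all(s.seed is not None for s in groups["neutral"])


class TestTrajectory:
    def test_hard_boundary_conditions(self):
        traj = simulate_trajectory(_scenario(tau=0.0), rng_seed=0)
        assert traj.frequencies[0] == 1.0
        assert traj.frequencies[-1] == pytest.approx(1 / 20_000)
        assert np.all((traj.frequencies >= 1 / 20_000) & (traj.frequencies <= 1.0))

    def test_fixation_period_held_at_one(self):
        traj = simulate_trajectory(_scenario(tau=500.0), rng_seed=0)
        assert np.all(traj.frequencies[:501] == 1.0)

    def test_soft_changepoint_frequency(self):
        traj = simulate_trajectory(_scenario("soft", f=0.2), rng_seed=1)
        change = traj.tau_generations + traj.sweep_phase_length
        assert traj.frequencies[change] == pytest.approx(0.2)
        assert traj.drift_phase_length > 0
        assert traj.frequencies[-1] == pytest.approx(1 / 20_000)

    def test_neutral_scenario_rejected(self):
        neutral = SweepScenario(true_class="neutral", demography=EQ, theta=THETA, rho=RHO)
        with pytest.raises(ValueError, match="sweep"):
            simulate_trajectory(neutral)

    def test_mean_sweep_duration_matches_forward_oracle(self):
        """Sweep-phase duration agrees with a brute-force conditioned
        Wright–Fisher forward simulation (alpha = 2500, N = 10,000)."""
        N, alpha = 10_000, 2500.0
        s_het = alpha / (2 * N)
        rng = np.random.default_rng(0)

        def oracle_duration():
            while True:
                p, gens = 1 / (2 * N), 0
                while 0 < p < 1:
                    p_star = p * (1 + s_het) / (1 + s_het * p)
                    p = rng.binomial(2 * N, p_star) / (2 * N)
                    gens += 1
                if p >= 1:
                    return gens

        oracle = np.array([oracle_duration() for _ in range(300)])
        ours = np.array(
            [
                simulate_trajectory(_scenario(alpha=alpha), rng_seed=k).sweep_phase_length
                for k in range(300)
            ]
        )
        se = np.sqrt(oracle.var() / 300 + ours.var() / 300)
        assert abs(ours.mean() - oracle.mean()) < 3 * se


def _central_window(sample):
    idx = partition_subwindows(sample.positions)[5]
    return sample.window(idx)


class TestSimulatedRegions:
    def test_sample_size_is_100_chromosomes(self):
        sample = simulate_region(_scenario(), rng_seed=4)
        assert sample.matrix.shape[0] == 100
        assert sample.polarized

    def test_every_site_segregating_and_positions_sorted(self):
        sample = simulate_region(_scenario("soft", f=0.1, tau=100.0), rng_seed=9)
        counts = sample.matrix.sum(axis=0)
        assert np.all((counts > 0) & (counts < 100))
        assert np.all(np.diff(sample.positions) >= 0)

    def test_hard_sweep_erases_central_diversity(self):
        """A strong, just-completed hard sweep leaves the central subwindow
        with a small fraction of the neutral diversity theta/11."""
        pis = []
        for k in range(25):
            sample = simulate_region(_scenario(tau=0.0), rng_seed=100 + k)
            pi, *_ = site_stats(_central_window(sample))
            pis.append(pi)
        assert np.median(pis) < 0.2 * THETA / 11

    def test_soft_sweep_converges_to_hard_as_f_vanishes(self):
        """At f = 2/(2N) the standing variant is effectively de novo: the
        number of distinct central haplotypes matches hard sweeps at the
        same alpha and tau within sampling error."""
        reps = 40
        k_hard, k_soft = [], []
        for k in range(reps):
            hard = simulate_region(_scenario(tau=0.0), rng_seed=500 + k)
            soft = simulate_region(
                _scenario("soft", f=1e-4, tau=0.0), rng_seed=900 + k
            )
            k_hard.append(haplotype_stats(_central_window(hard))[0])
            k_soft.append(haplotype_stats(_central_window(soft))[0])
        k_hard, k_soft = np.array(k_hard, float), np.array(k_soft, float)
        se = np.sqrt(k_hard.var() / reps + k_soft.var() / reps)
        assert abs(k_hard.mean() - k_soft.mean()) < 3 * se

    def test_diversity_recovers_with_sweep_age(self):
        """Mean central pi increases monotonically in the fixation time."""
        means = []
        for tau in (0.0, 1000.0, 2000.0):
            pis = [
                site_stats(
                    _central_window(
                        simulate_region(_scenario(tau=tau), rng_seed=2000 + k)
                    )
                )[0]
                for k in range(200)
            ]
            means.append(np.mean(pis))
        assert means[0] < means[1] < means[2]
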