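"""Coalescent simulation of neutral, hard-sweep and soft-sweep regions.

Training data are simulated as large chromosomal windows that are later split
into 11 adjacent, equally sized subwindows.  A sweep can be placed in the
centre of any subwindow: centrally swept windows are the "hard"/"soft"
classes, windows whose sweep lies in a non-central subwindow are the
"hard-linked"/"soft-linked" classes, and windows without a sweep are
"neutral".

The coalescent machinery is delegated to msprime for the neutral history
and the sweep phase proper (its structured-coalescent sweep model follows
discoal).  The selection scale alpha = 2Ns (s the heterozygote advantage)
translates to msprime's convention (genotype fitnesses 1, 1+s/2, 1+s) as
``s_msprime = alpha / N``.

Standing-variant (soft) sweeps additionally require the drift phase: below
the onset frequency f the lineages carrying the selected site are confined
to a derived class of shrinking size f(t) N, which msprime cannot simulate.
That phase is implemented here: the simulation is stopped at sweep onset,
the live lineages ancestral at the selected site are evolved under a
structured coalescent along a conditioned Wright–Fisher frequency path
(pairwise coalescence at rate 1/(2 N f(t)), recombination freeing flanking
material at the per-generation map rate), and msprime resumes from the
resulting tree sequence for the deep history.

msprime also cannot change the population size during a sweep epoch, so for
non-equilibrium histories the size is held at the harmonic mean of N(t)
over the expected sweep duration; the true size history resumes immediately
after the sweep.  See docs/methods.md for the accuracy discussion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import msprime
import numpy as np
import tskit

from msprime._msprime import LibraryError as _MsprimeLibraryError

from .demography import DemographicModel, get_model
from .samples import HaplotypeSample

__all__ = [
    "SWEEP_CLASSES",
    "SweepScenario",
    "Trajectory",
    "SimulationConfig",
    "simulate_trajectory",
    "simulate_region",
    "build_scenario_set",
    "build_training_scenarios",
    "bottleneck_fixation_presets",
]

SWEEP_CLASSES = ("hard", "hard-linked", "soft", "soft-linked", "neutral")

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SweepScenario:
    """Parameters of a single simulated region.

    ``theta`` and ``rho`` are population-scaled rates for the whole
    11-subwindow locus (4 N_ref mu L and 4 N_ref r L).  ``tau`` is the sweep
    completion time in generations before sampling; ``f`` the derived-allele
    frequency at sweep onset (standing-variant sweeps only).
    """

    true_class: str
    demography: DemographicModel
    theta: float
    rho: float
    sample_size: int = 100
    n_subwindows: int = 11
    alpha: float | None = None
    f: float | None = None
    tau: float | None = None
    sweep_subwindow: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.true_class not in SWEEP_CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.theta <= 0 or self.rho < 0:
            raise ValueError("theta must be positive and rho nonnegative")
        if self.sample_size < 2 or self.sample_size % 2:
            raise ValueError("sample_size must be an even number of chromosomes >= 2")
        centre = self.n_subwindows // 2
        if self.true_class == "neutral":
            if any(v is not None for v in (self.alpha, self.f, self.tau, self.sweep_subwindow)):
                raise ValueError("neutral scenarios carry no sweep parameters")
            return
        if self.alpha is None or self.alpha <= 0:
            raise ValueError("sweep scenarios require alpha > 0")
        if self.tau is None or self.tau < 0:
            raise ValueError("sweep scenarios require a fixation time tau >= 0")
        if self.sweep_subwindow is None or not 0 <= self.sweep_subwindow < self.n_subwindows:
            raise ValueError("sweep_subwindow must be in [0, n_subwindows)")
        centred = self.sweep_subwindow == centre
        if self.true_class in ("hard", "soft") and not centred:
            raise ValueError("hard/soft scenarios must have the sweep in the central subwindow")
        if self.true_class.endswith("-linked") and centred:
            raise ValueError("linked scenarios must have the sweep off-centre")
        if self.true_class.startswith("hard"):
            if self.f is not None:
                raise ValueError("hard sweeps have no standing frequency f")
        else:
            N = self.demography.reference_size
            if self.f is None or not (1.0 / N <= self.f < 1.0):
                raise ValueError("soft sweeps require 2/(2N) <= f < 1")

    @property
    def sweep_position(self) -> float:
        """Selected-site position on the unit locus: (2j + 1) / (2 n_sub)."""
        if self.sweep_subwindow is None:
            raise ValueError("neutral scenario has no sweep position")
        return (2 * self.sweep_subwindow + 1) / (2 * self.n_subwindows)

    @property
    def is_sweep(self) -> bool:
        return self.true_class != "neutral"


@dataclass(frozen=True)
class Trajectory:
    """Allele-frequency path of the selected allele, one value per generation
    from the present (index 0) back to the allele's origin."""

    frequencies: np.ndarray
    tau_generations: int
    sweep_phase_length: int
    drift_phase_length: int


def _conditioned_wf_path(
    p0: float,
    target: float,
    s_het: float,
    N: int,
    rng: np.random.Generator,
    max_attempts: int = 200_000,
) -> list[float]:
    """Forward Wright–Fisher path from p0, rejection-conditioned on reaching
    ``target`` before loss.  Genic selection: p* = p(1+s)/(1+sp)."""
    two_n = 2 * N
    for _ in range(max_attempts):
        p = p0
        path = [p0]
        while 0.0 < p < target:
            p_star = p * (1.0 + s_het) / (1.0 + s_het * p)
            p = rng.binomial(two_n, min(p_star, 1.0)) / two_n
            path.append(p)
        if p >= target:
            path[-1] = target  # clamp the crossing generation to the boundary
            return path
    raise RuntimeError("conditioned trajectory failed to reach the target frequency")


def simulate_trajectory(scenario: SweepScenario, rng_seed: int = 0) -> Trajectory:
    """Jump-process trajectory of the selected allele, backward in time.

    Frequency 1.0 is held for tau generations (post-fixation), then the sweep
    phase descends from 1 to f (hard sweeps: to 1/(2N)) under genic selection
    of strength alpha = 2Ns, and for standing-variant sweeps a neutral drift
    phase continues from f down to 1/(2N).  Both phases are per-generation
    binomial Wright–Fisher updates, rejection-conditioned on the allele
    fixing (respectively surviving to frequency f).  The population size is
    held at the demography's reference size.
    """
    if not scenario.is_sweep:
        raise ValueError("simulate_trajectory requires a sweep scenario")
    N = int(round(scenario.demography.reference_size))
    s_het = scenario.alpha / (2.0 * N)
    rng = np.random.default_rng(rng_seed)
    f0 = scenario.f if scenario.true_class.startswith("soft") else 1.0 / (2 * N)
    sweep_fwd = _conditioned_wf_path(f0, 1.0, s_het, N, rng)
    drift_fwd: list[float] = []
    if scenario.true_class.startswith("soft"):
        drift_fwd = _conditioned_wf_path(1.0 / (2 * N), scenario.f, 0.0, N, rng)
    n_tau = int(round(scenario.tau))
    parts = [np.ones(n_tau), np.asarray(sweep_fwd[::-1])]
    if drift_fwd:
        parts.append(np.asarray(drift_fwd[::-1][1:]))  # drop duplicated changepoint
    freqs = np.concatenate(parts)
    return Trajectory(
        frequencies=freqs,
        tau_generations=n_tau,
        sweep_phase_length=len(sweep_fwd) - 1,
        drift_phase_length=max(len(drift_fwd) - 1, 0),
    )


def _logistic_sweep_duration(s_het: float, N: float, f0: float) -> float:
    """Deterministic duration of a sweep from f0 to 1 - 1/(2N), generations."""
    eps = 1.0 / (2.0 * N)
    f0 = min(max(f0, eps), 1.0 - eps)
    return (math.log((1.0 - eps) / eps) + math.log((1.0 - f0) / f0)) / s_het


def _sweep_simulation_pieces(scenario: SweepScenario, buffer_factor: float = 4.0):
    """Frozen-size demography plus the msprime model list for a sweep.

    The model list ends with the sweep, so the simulation stops at sweep
    onset; the drift phase (soft sweeps) and the deep neutral history are
    handled afterwards by the caller.
    """
    demog = scenario.demography
    N_ref = demog.reference_size
    s_het = scenario.alpha / (2.0 * N_ref)
    tau = float(scenario.tau)
    # self-consistent harmonic-mean size over the expected sweep interval
    N_h = demog.size_at(tau)
    f0 = scenario.f if scenario.true_class.startswith("soft") else None
    for _ in range(3):
        start = f0 if f0 is not None else 1.0 / (2.0 * N_h)
        T = _logistic_sweep_duration(s_het, N_h, start)
        N_h = demog.harmonic_mean_size(tau, tau + T)
    start = max(f0 if f0 is not None else 0.0, 1.0 / (2.0 * N_h))
    T = _logistic_sweep_duration(s_het, N_h, start)
    buffer = buffer_factor * T + 200.0
    models: list = []
    if tau > 0:
        models.append(msprime.StandardCoalescent(duration=tau))
    models.append(
        msprime.SweepGenicSelection(
            position=scenario.sweep_position,
            start_frequency=start,
            end_frequency=1.0 - 1.0 / (2.0 * N_h),
            s=2.0 * s_het,  # msprime's s is twice the heterozygote advantage
            dt=1.0 / (40.0 * N_h),
        )
    )
    frozen = demog.to_msprime(freeze=(tau, tau + buffer, N_h))
    return frozen, models, N_h


# -- standing-variation drift phase -----------------------------------------


@dataclass
class _Lineage:
    node: int
    intervals: list[tuple[float, float]]
    epoch_start: float = 0.0  # virtual generation when the current material epoch began
    epochs: list[tuple[list[tuple[float, float]], float]] = field(default_factory=list)

    @property
    def span(self) -> tuple[float, float]:
        return self.intervals[0][0], self.intervals[-1][1]

    def close_epoch(self, g: float) -> None:
        if g > self.epoch_start:
            self.epochs.append((self.intervals, g - self.epoch_start))
        self.epoch_start = g


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    intervals = sorted(intervals)
    out = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _clip_intervals(intervals, lo, hi):
    return [(max(a, lo), min(b, hi)) for a, b in intervals if a < hi and b > lo]


def _drift_frequency_path(
    f: float, N_d: float, rng: np.random.Generator, n_traj: int = 1000
) -> tuple[np.ndarray, int]:
    """Backward frequency path from f down to 1/(2 N_d), coarse-grained.

    Returns ``(freqs, stretch)``: each entry of ``freqs`` applies for
    ``stretch`` real generations.  The conditioned Wright–Fisher path is
    simulated at a reduced size ``n_traj`` (the neutral-drift diffusion is
    invariant under this rescaling) and stretched back to the true time
    scale; below the rescaled resolution 1/(2 n_traj) the path continues
    with a deterministic geometric tail to the allele's single-copy origin,
    whose duration matches the conditioned sojourn time ~4 N x ln(1/x) —
    the low-frequency generations in which flanking material can still
    recombine away while the class coalesces.
    """
    n_traj = int(min(n_traj, N_d))
    stretch = max(int(round(N_d / n_traj)), 1)
    x_origin = 1.0 / (2.0 * N_d)
    x_trunc = min(f, 1.0 / (2 * n_traj))
    parts = []
    if f > 1.0 / (2 * n_traj):
        forward = _conditioned_wf_path(1.0 / (2 * n_traj), f, 0.0, n_traj, rng)
        parts.append(np.asarray(forward[::-1]))
    if x_trunc > x_origin:
        tail_gens = 4.0 * N_d * x_trunc * max(math.log(1.0 / x_trunc), 1.0)
        n_steps = max(int(round(tail_gens / stretch)), 1)
        parts.append(np.geomspace(x_trunc, x_origin, n_steps + 1)[1:])
    if not parts:
        return np.empty(0), stretch
    return np.concatenate(parts), stretch


def _run_drift_phase(
    ts: tskit.TreeSequence,
    scenario: SweepScenario,
    t0: float,
    r_rate: float,
    rng: np.random.Generator,
) -> tuple[tskit.TableCollection, float, list[tuple[float, int]]]:
    """Structured coalescent for the derived class below frequency f.

    Backward from the sweep-onset time ``t0`` the lineages ancestral at the
    selected site (necessarily carrying the derived allele) coalesce
    pairwise at rate 1/(2 N f(t)) while recombination at the map rate frees
    flanking material, which rejoins the neutral background and is picked up
    again when the standard coalescent resumes.  f(t) follows a conditioned
    Wright–Fisher path from f down to the allele's origin, where any
    remaining derived lineages merge.

    The race between restricted coalescence and recombination is simulated
    in virtual drift generations but its events are recorded compressed
    into an infinitesimal window just above ``t0``: the outcome of the race
    depends only on the relative rates, and compressing it means the
    neutral background resumes coalescing immediately instead of idling
    (which would spuriously inflate diversity).  The mutations that the
    sweeping haplotypes accumulate during the drift generations are
    returned as ``(position, node)`` pairs, sampled from each lineage's
    material-by-duration exposure, and are added to the site table after
    neutral mutation simulation.
    """
    x_sel = scenario.sweep_position
    demog = scenario.demography
    # size governing the drift phase, iterated to its own harmonic mean
    N_d = demog.size_at(t0)
    for _ in range(2):
        N_d = demog.harmonic_mean_size(t0, t0 + 4.0 * N_d * scenario.f)
    freqs, stretch = _drift_frequency_path(scenario.f, N_d, rng)

    # live lineages = root nodes at the stop time; derived = material at x_sel
    material: dict[int, list[tuple[float, float]]] = {}
    derived_nodes: set[int] = set()
    node_time = ts.tables.nodes.time
    for tree in ts.trees():
        left, right = tree.interval
        for root in tree.roots:
            if node_time[root] != t0:
                continue
            material.setdefault(root, []).append((left, right))
            if left <= x_sel < right:
                derived_nodes.add(root)
    lineages = [
        _Lineage(node, _merge_intervals(iv))
        for node, iv in material.items()
        if node in derived_nodes
    ]
    tables = ts.dump_tables()
    exposures: list[tuple[list[tuple[float, float]], float, int]] = []
    eps = 1e-6
    n_events = 0

    def coalesce(i: int, j: int, g: float):
        nonlocal lineages, n_events
        n_events += 1
        u, v = lineages[i], lineages[j]
        w = tables.nodes.add_row(flags=0, time=t0 + n_events * eps, population=0)
        for child in (u, v):
            child.close_epoch(g)
            for iv, dur in child.epochs:
                exposures.append((iv, dur, child.node))
            for lo, hi in child.intervals:
                tables.edges.add_row(left=lo, right=hi, parent=w, child=child.node)
        merged = _Lineage(w, _merge_intervals(u.intervals + v.intervals), epoch_start=g)
        lineages = [li for idx, li in enumerate(lineages) if idx not in (i, j)] + [merged]

    def rates(f_g):
        k = len(lineages)
        copies = 2.0 * N_d * f_g
        lam_coal = (k * (k - 1) / 2.0) / copies if copies > 1.0 else float("inf")
        spans = [li.span[1] - li.span[0] for li in lineages]
        lam_rec = r_rate * sum(spans)
        return lam_coal, lam_rec, spans

    def one_event(f_g, g, lam_coal, lam_rec, spans):
        if lam_coal == float("inf") or rng.random() < lam_coal / (lam_coal + lam_rec):
            i, j = rng.choice(len(lineages), size=2, replace=False)
            coalesce(int(i), int(j), g)
        else:
            idx = rng.choice(len(lineages), p=np.asarray(spans) / sum(spans))
            li = lineages[int(idx)]
            lo, hi = li.span
            brk = rng.uniform(lo, hi)
            keep = (
                _clip_intervals(li.intervals, brk, np.inf)
                if x_sel >= brk
                else _clip_intervals(li.intervals, -np.inf, brk)
            )
            if keep:
                li.close_epoch(g)
                li.intervals = keep

    # per-generation Bernoulli event process, with geometric skip-ahead
    # within each coarse step (the rate is constant between events there)
    g = 0.0
    for step in range(freqs.size):
        if len(lineages) <= 1:
            break
        f_g = freqs[step]
        remaining = stretch
        while remaining > 0 and len(lineages) > 1:
            lam_coal, lam_rec, spans = rates(f_g)
            p = min(lam_coal + lam_rec, 1.0)
            if p <= 0.0:
                g += remaining
                break
            if p >= 1.0:
                advance = 1
            else:
                advance = int(rng.geometric(p))
            if advance > remaining:
                g += remaining
                break
            g += advance
            remaining -= advance
            one_event(f_g, g, lam_coal, lam_rec, spans)
    # the allele's origin: any remaining derived lineages share their MRCA
    while len(lineages) > 1:
        coalesce(0, 1, g)
    for li in lineages:
        li.close_epoch(float(g))
        for iv, dur in li.epochs:
            exposures.append((iv, dur, li.node))
    u_rate = scenario.theta / (4.0 * scenario.demography.reference_size)
    drift_mutations: list[tuple[float, int]] = []
    for intervals, duration, node in exposures:
        lengths = np.array([hi - lo for lo, hi in intervals])
        total_len = lengths.sum()
        for _ in range(rng.poisson(u_rate * total_len * duration)):
            which = rng.choice(len(intervals), p=lengths / total_len)
            lo, hi = intervals[which]
            drift_mutations.append((rng.uniform(lo, hi), node))
    tables.sort()
    t_end = t0 + (n_events + 1) * eps
    return tables, t_end, drift_mutations


def _insert_drift_mutations(
    ts: tskit.TreeSequence, drift_mutations: list[tuple[float, int]]
) -> tskit.TreeSequence:
    """Append standing-phase mutations as new biallelic sites."""
    if not drift_mutations:
        return ts
    tables = ts.dump_tables()
    existing = set(np.round(ts.sites_position, 12).tolist())
    for pos, node in drift_mutations:
        if round(pos, 12) in existing:
            continue
        site = tables.sites.add_row(position=pos, ancestral_state="0")
        tables.mutations.add_row(
            site=site, node=node, derived_state="1", time=tskit.UNKNOWN_TIME
        )
    tables.sort()
    return tables.tree_sequence()


def simulate_region(scenario: SweepScenario, rng_seed: int | None = None) -> HaplotypeSample:
    """Simulate one haplotype sample over the unit locus.

    Neutral scenarios run the standard coalescent under the scenario's
    demography.  Sweep scenarios prepend tau generations of neutral history,
    run the structured-coalescent sweep model with the selected site at
    ``scenario.sweep_position``, then (soft sweeps) the standing-variant
    drift phase, and finally resume the standard coalescent under the
    original demography for the deep history.  Mutation and recombination
    rates are ``theta / (4 N_ref)`` and ``rho / (4 N_ref)`` per unit locus
    per generation, so the realized locus-wide scaled rates equal theta and
    rho.
    """
    seed = rng_seed if rng_seed is not None else scenario.seed
    if seed is None:
        raise ValueError("a seed is required (scenario.seed or rng_seed)")
    anc_seed, mut_seed, resume_seed, drift_seed = _split_seed(seed, 4)
    N_ref = scenario.demography.reference_size
    r_rate = scenario.rho / (4.0 * N_ref)
    common = dict(
        sequence_length=1.0,
        recombination_rate=r_rate,
        discrete_genome=False,
    )
    if not scenario.is_sweep:
        ts = msprime.sim_ancestry(
            samples=scenario.sample_size // 2,
            ploidy=2,
            demography=scenario.demography.to_msprime(),
            random_seed=anc_seed,
            **common,
        )
    else:
        buffer_factor = 4.0
        last_err: Exception | None = None
        for _ in range(6):
            demog, models, _ = _sweep_simulation_pieces(scenario, buffer_factor)
            try:
                partial = msprime.sim_ancestry(
                    samples=scenario.sample_size // 2,
                    ploidy=2,
                    demography=demog,
                    model=models,
                    random_seed=anc_seed,
                    **common,
                )
                break
            except (tskit.LibraryError, _MsprimeLibraryError) as err:  # buffer too short
                last_err = err
                buffer_factor *= 2.0
        else:
            raise RuntimeError(f"sweep simulation failed repeatedly: {last_err}")
        t0 = partial.max_root_time
        drift_mutations: list[tuple[float, int]] = []
        if scenario.true_class.startswith("soft"):
            rng = np.random.default_rng(drift_seed)
            tables, t_end, drift_mutations = _run_drift_phase(
                partial, scenario, t0, r_rate, rng
            )
            partial = tables.tree_sequence()
        else:
            t_end = t0
        ts = msprime.sim_ancestry(
            initial_state=partial,
            demography=scenario.demography.to_msprime(),
            start_time=t_end,
            random_seed=resume_seed,
            **common,
        )
    ts = msprime.sim_mutations(
        ts,
        rate=scenario.theta / (4.0 * N_ref),
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=mut_seed,
    )
    if scenario.is_sweep and scenario.true_class.startswith("soft"):
        ts = _insert_drift_mutations(ts, drift_mutations)
    matrix = ts.genotype_matrix().T.astype(np.uint8)
    positions = ts.sites_position.copy()
    # drift-phase bookkeeping does not track local MRCAs, so mutations can
    # land above them; drop the resulting non-segregating columns
    counts = matrix.sum(axis=0)
    seg = (counts > 0) & (counts < matrix.shape[0])
    return HaplotypeSample(
        matrix=matrix[:, seg],
        positions=positions[seg],
        polarized=True,
        metadata={"true_class": scenario.true_class, "seed": seed},
    )


def _split_seed(seed: int, n: int = 2) -> tuple[int, ...]:
    children = np.random.SeedSequence(seed).spawn(n)
    return tuple(int(c.generate_state(1)[0] % _MAX_SEED) + 1 for c in children)


# ---------------------------------------------------------------------------
# scenario-set construction


def bottleneck_fixation_presets(N: float) -> dict[str, float]:
    """The three fixation-time presets for the bottleneck models."""
    return {"recent": 0.0, "mid": 0.022 * 2 * N, "old": 0.044 * 2 * N}


@dataclass
class SimulationConfig:
    """Prior ranges and sizes for one batch of training/test simulations.

    Defaults follow the training design: 100 chromosomes, 11 subwindows,
    equilibrium per-subwindow theta = 50 and rho = 80 (population-scaled,
    fixed), soft-sweep onset frequency f ~ U(0.05, 0.2) at equilibrium and
    U(2/(2N), 0.2) otherwise, fixation time tau ~ U(0, 0.2 N) generations at
    equilibrium, within the growth phase for the human models (<= ~5.1 kya
    African, <= 51 kya European), and a fixed preset for the bottlenecks.
    Human models draw locus-wide theta and rho from truncated normal priors
    whose means match mu = 1.2e-8 and r = 1e-8 per bp per generation at
    200 kb subwindows.
    """

    demography: DemographicModel | str = "equilibrium"
    alpha_range: tuple[float, float] | None = None
    f_range: tuple[float, float] | None = None
    reps: int = 1000
    sample_size: int = 100
    n_subwindows: int = 11
    theta_per_subwindow: float = 50.0
    rho_per_subwindow: float = 80.0
    subwindow_bp: int = 200_000
    mu_per_bp: float = 1.2e-8
    r_per_bp: float = 1.0e-8
    rate_prior_cv: float = 0.2  # coefficient of variation of the theta/rho priors
    fixation_time: float | str | None = None  # bottleneck presets or explicit tau
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.demography, str):
            self.demography = get_model(self.demography)
        if self.alpha_range is not None and self.alpha_range[0] >= self.alpha_range[1]:
            raise ValueError("alpha_range must satisfy low < high")

    # -- prior draws -------------------------------------------------------

    @property
    def _is_human(self) -> bool:
        return self.demography.label in ("african_growth", "european_tennessen")

    def draw_rates(self, rng: np.random.Generator) -> tuple[float, float]:
        """Locus-wide (theta, rho) for one scenario."""
        n_sub = self.n_subwindows
        if not self._is_human:
            return self.theta_per_subwindow * n_sub, self.rho_per_subwindow * n_sub
        N = self.demography.reference_size
        L = self.subwindow_bp * n_sub
        out = []
        for per_bp in (self.mu_per_bp, self.r_per_bp):
            mean = 4.0 * N * per_bp * L
            out.append(_truncated_normal(rng, mean, self.rate_prior_cv * mean, 0.5 * mean, 2.0 * mean))
        return out[0], out[1]

    def draw_tau(self, rng: np.random.Generator) -> float:
        if self.fixation_time is not None:
            if isinstance(self.fixation_time, str):
                presets = bottleneck_fixation_presets(self.demography.reference_size)
                return presets[self.fixation_time]
            return float(self.fixation_time)
        label = self.demography.label
        if label == "african_growth":
            return rng.uniform(0.0, 5115.0 / 25.0)
        if label == "european_tennessen":
            return rng.uniform(0.0, 51_000.0 / 25.0)
        if label.startswith("bottleneck"):
            return 0.0  # "recent" preset unless overridden
        return rng.uniform(0.0, 0.2 * self.demography.reference_size)

    def draw_f(self, rng: np.random.Generator) -> float:
        if self.f_range is not None:
            lo, hi = self.f_range
        elif self.demography.label == "equilibrium":
            lo, hi = 0.05, 0.2
        else:
            lo, hi = 1.0 / self.demography.reference_size, 0.2
        return rng.uniform(lo, hi)


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(mean)


def _draw_scenario(
    config: SimulationConfig,
    kind: str,
    subwindow: int | None,
    rng: np.random.Generator,
    seed_seq: np.random.SeedSequence,
) -> SweepScenario:
    theta, rho = config.draw_rates(rng)
    seed = int(seed_seq.generate_state(1)[0] % _MAX_SEED) + 1
    base = dict(
        demography=config.demography,
        theta=theta,
        rho=rho,
        sample_size=config.sample_size,
        n_subwindows=config.n_subwindows,
        seed=seed,
    )
    if kind == "neutral":
        return SweepScenario(true_class="neutral", **base)
    if config.alpha_range is None:
        raise ValueError("sweep scenarios require an alpha_range")
    centre = config.n_subwindows // 2
    label = kind if subwindow == centre else f"{kind}-linked"
    alpha = rng.uniform(*config.alpha_range)
    tau = config.draw_tau(rng)
    f = config.draw_f(rng) if kind == "soft" else None
    return SweepScenario(
        true_class=label, alpha=alpha, f=f, tau=tau, sweep_subwindow=subwindow, **base
    )


def build_scenario_set(config: SimulationConfig) -> list[SweepScenario]:
    """The full training design: R hard sweeps in each of the 11 subwindows,
    R soft sweeps per subwindow, and R neutral regions (23 R scenarios)."""
    rng = np.random.default_rng(config.seed)
    root = np.random.SeedSequence(config.seed)
    scenarios: list[SweepScenario] = []
    children = iter(root.spawn(config.reps * (2 * config.n_subwindows + 1)))
    for kind in ("hard", "soft"):
        for j in range(config.n_subwindows):
            for _ in range(config.reps):
                scenarios.append(_draw_scenario(config, kind, j, rng, next(children)))
    for _ in range(config.reps):
        scenarios.append(_draw_scenario(config, "neutral", None, rng, next(children)))
    return scenarios


def build_training_scenarios(
    config: SimulationConfig, reps_per_class: int | None = None
) -> dict[str, list[SweepScenario]]:
    """Balanced five-class scenario draw, R per class.

    Linked-class sweep positions are sampled uniformly from the 10
    non-central subwindows — distributionally identical to drawing R of the
    10R non-central simulations of the full design, at a tenth of the cost.
    """
    R = reps_per_class if reps_per_class is not None else config.reps
    rng = np.random.default_rng(config.seed)
    root = np.random.SeedSequence(config.seed)
    children = iter(root.spawn(5 * R))
    centre = config.n_subwindows // 2
    offcentre = [j for j in range(config.n_subwindows) if j != centre]
    out: dict[str, list[SweepScenario]] = {c: [] for c in SWEEP_CLASSES}
    for _ in range(R):
        out["hard"].append(_draw_scenario(config, "hard", centre, rng, next(children)))
    for _ in range(R):
        out["soft"].append(_draw_scenario(config, "soft", centre, rng, next(children)))
    for _ in range(R):
        j = int(rng.choice(offcentre))
        out["hard-linked"].append(_draw_scenario(config, "hard", j, rng, next(children)))
    for _ in range(R):
        j = int(rng.choice(offcentre))
        out["soft-linked"].append(_draw_scenario(config, "soft", j, rng, next(children)))
    for _ in range(R):
        out["neutral"].append(_draw_scenario(config, "neutral", None, rng, next(children)))
    return out
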