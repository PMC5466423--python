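"""Stochastic, lineage-resolved simulation of symbiont serial passage.

Models a bacterial symbiont population through the stages of a host-passage
evolution experiment: exponential inoculum growth by binary fission, a narrow
recruitment bottleneck into each host's light organ (~12 founder cells), growth
to the light-organ carrying capacity (~5e5 cells), daily venting that removes
~95% of the population, and serial transfer of the ventate to a new host.

Fitness convention (simulator scale): a genotype with selection coefficient s
multiplies by ``2**(1 + s)`` per generation while the ancestor (s = 0) doubles.
This is the convention the analytic survival approximation presumes
(:mod:`bottlepass.survival`); the competition estimator's scale
(s = s_GR / ln 2) is distinct, and :mod:`bottlepass.fitness` exposes explicit
converters between the two.

Stochasticity: growth realizes the fractional part of the expected offspring
count by a Poisson draw; genotypes at or above ``STOCHASTIC_CUTOFF`` cells
update deterministically (rounded expectation) while rare lineages remain fully
stochastic, so rare-lineage drift is exact at desk-scale runtime. Bottlenecks
are binomial (fractional venting) or multivariate hypergeometric (fixed-size
recruitment). All randomness flows from a single ``numpy.random.Generator``;
identical seeds give identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UsageError
from .survival import LN2, BottleneckRegime, _tau_of

__all__ = [
    "Genotype",
    "PopulationState",
    "PassageScheme",
    "MutationParams",
    "Trajectory",
    "MutantFateResult",
    "founding_state",
    "grow_one_generation",
    "apply_fractional_bottleneck",
    "apply_fixed_bottleneck",
    "grow_to_capacity",
    "run_host_cycle",
    "run_passage_series",
    "mutant_fate_monte_carlo",
]

#: Genotypes at or above this cell count update deterministically during growth.
STOCHASTIC_CUTOFF = 1000

ANCESTOR_ID = 0


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class Genotype:
    """A lineage: unique id, selection coefficient (simulator scale), ancestry."""

    id: int
    s: float
    parent_id: Optional[int] = None
    origin_generation: int = 0


@dataclass
class PopulationState:
    """Per-genotype cell counts at a given generation and phase."""

    counts: Dict[int, int]
    genotypes: Dict[int, Genotype]
    generation: int = 0
    phase: str = "inoculum"

    def __post_init__(self) -> None:
        for gid, n in self.counts.items():
            if n < 0 or int(n) != n:
                raise DomainError(f"count for genotype {gid} must be a non-negative integer")
            if gid not in self.genotypes:
                raise UsageError(f"genotype {gid} has a count but no registry entry")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def frequencies(self) -> Dict[int, float]:
        tot = self.total
        if tot == 0:
            return {}
        return {gid: n / tot for gid, n in self.counts.items() if n > 0}

    def selection_of(self, gid: int) -> float:
        return self.genotypes[gid].s


def founding_state(n0: int, phase: str = "inoculum", s_ancestor: float = 0.0) -> PopulationState:
    """A single-ancestor population of ``n0`` cells at generation zero."""
    if n0 < 1:
        raise DomainError(f"founding population must have at least one cell, got {n0}")
    anc = Genotype(ANCESTOR_ID, s_ancestor, None, 0)
    return PopulationState({ANCESTOR_ID: int(n0)}, {ANCESTOR_ID: anc}, 0, phase)


@dataclass(frozen=True)
class PassageScheme:
    """Growth/bottleneck regime of one serial-passage evolution experiment.

    Defaults follow the squid-Vibrio experiment: a 5-cell inoculum grown to
    2.4e8 cells (~25 generations), 12-cell recruitment into each light organ,
    growth to the 5e5-cell organ capacity, 95% venting at dawn, four
    vent/regrow cycles per host, 15 hosts in series.
    """

    n0: int = 5
    n_inoc: int = 240_000_000
    recruitment_size: int = 12
    carrying_capacity: int = 500_000
    venting_survival_fraction: float = 0.05
    cycles_per_host: int = 4
    n_hosts: int = 15
    tau_recruitment: int = 25
    tau_venting: int = 4

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise DomainError("n0 must be >= 1")
        if self.n_inoc <= self.n0:
            raise DomainError("n_inoc must exceed n0")
        if not 0.0 < self.venting_survival_fraction < 1.0:
            raise DomainError("venting_survival_fraction must lie in (0, 1)")
        if self.recruitment_size < 1:
            raise DomainError("recruitment_size must be >= 1")
        if self.carrying_capacity < self.recruitment_size:
            raise DomainError("carrying_capacity must be >= recruitment_size")
        if self.cycles_per_host < 0 or self.n_hosts < 0:
            raise DomainError("cycles_per_host and n_hosts must be >= 0")
        if self.tau_recruitment < 1 or self.tau_venting < 1:
            raise DomainError("tau values must be >= 1")


@dataclass(frozen=True)
class MutationParams:
    """Per-cell-division mutation rate into the focal beneficial class."""

    mu_locus: float = 0.0
    s_new: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_locus < 0:
            raise DomainError("mu_locus must be >= 0")


NO_MUTATION = MutationParams(0.0, 0.0)


def _offspring(n: int, s: float, rng: np.random.Generator, deterministic: bool) -> int:
    """Offspring count for a genotype of ``n`` cells with coefficient ``s``."""
    f = 2.0 ** (1.0 + s)
    if deterministic or n >= STOCHASTIC_CUTOFF:
        return int(round(n * f))
    base = math.floor(f)
    frac = f - base
    extra = int(rng.poisson(n * frac)) if frac > 0 else 0
    return n * base + extra


def grow_one_generation(
    state: PopulationState,
    mut: MutationParams = NO_MUTATION,
    rng=None,
    *,
    deterministic: bool = False,
) -> PopulationState:
    """Advance the population one generation of binary-fission growth.

    The ancestor doubles; a genotype with coefficient s multiplies by
    ``2**(1+s)`` (fraction realized by a Poisson draw in stochastic mode).
    New mutants are drawn Poisson(mu_locus x cell divisions this generation),
    each seeded as a one-cell lineage with coefficient ``mut.s_new``; the
    number of divisions is the net increase in cell count.
    """
    rng = _as_rng(rng)
    new_counts: Dict[int, int] = {}
    for gid in sorted(state.counts):
        n = state.counts[gid]
        if n <= 0:
            continue
        new_counts[gid] = _offspring(n, state.genotypes[gid].s, rng, deterministic)
    genotypes = dict(state.genotypes)
    divisions = max(sum(new_counts.values()) - state.total, 0)
    if mut.mu_locus > 0 and divisions > 0:
        n_new = int(rng.poisson(mut.mu_locus * divisions))
        if n_new > 0:
            ids = sorted(gid for gid, n in new_counts.items() if n > 0)
            weights = np.array([new_counts[g] for g in ids], dtype=float)
            weights /= weights.sum()
            parents = rng.choice(ids, size=n_new, p=weights)
            next_id = max(genotypes) + 1
            for parent in parents:
                parent = int(parent)
                genotypes[next_id] = Genotype(
                    next_id, mut.s_new, parent, state.generation + 1
                )
                new_counts[next_id] = 1
                if new_counts[parent] > 0:
                    new_counts[parent] -= 1  # the mutant daughter replaces one
                next_id += 1
    return PopulationState(new_counts, genotypes, state.generation + 1, state.phase)


def apply_fractional_bottleneck(
    state: PopulationState, fraction: float, rng=None
) -> PopulationState:
    """Each cell survives independently with probability ``fraction`` (venting)."""
    if not 0.0 < fraction <= 1.0:
        raise DomainError(f"fraction must lie in (0, 1], got {fraction!r}")
    if fraction == 1.0:
        return replace(state, counts=dict(state.counts))
    rng = _as_rng(rng)
    new_counts = {}
    for gid in sorted(state.counts):
        n = state.counts[gid]
        if n <= 0:
            continue
        survivors = int(rng.binomial(n, fraction))
        if survivors > 0:
            new_counts[gid] = survivors
    return replace(state, counts=new_counts)


def apply_fixed_bottleneck(state: PopulationState, size: int, rng=None) -> PopulationState:
    """Draw exactly ``size`` cells without replacement (recruitment bottleneck)."""
    total = state.total
    if not 1 <= size <= total:
        raise DomainError(f"bottleneck size must satisfy 1 <= size <= total={total}, got {size}")
    rng = _as_rng(rng)
    ids = sorted(gid for gid, n in state.counts.items() if n > 0)
    colors = np.array([state.counts[g] for g in ids], dtype=np.int64)
    draw = rng.multivariate_hypergeometric(colors, size, method="marginals")
    new_counts = {gid: int(k) for gid, k in zip(ids, draw) if k > 0}
    return replace(state, counts=new_counts)


def _truncate_to(state: PopulationState, capacity: int) -> PopulationState:
    """Proportional largest-remainder truncation of an overshoot to ``capacity``."""
    total = state.total
    if total <= capacity:
        return state
    ids = sorted(gid for gid, n in state.counts.items() if n > 0)
    shares = np.array([state.counts[g] for g in ids], dtype=float) * (capacity / total)
    floors = np.floor(shares).astype(np.int64)
    deficit = capacity - int(floors.sum())
    if deficit > 0:
        order = np.lexsort((ids, -(shares - floors)))  # largest remainder, ties by id
        floors[order[:deficit]] += 1
    new_counts = {gid: int(k) for gid, k in zip(ids, floors) if k > 0}
    return replace(state, counts=new_counts)


def grow_to_capacity(
    state: PopulationState,
    capacity: int,
    mut: MutationParams = NO_MUTATION,
    rng=None,
    *,
    deterministic: bool = False,
    max_generations: Optional[int] = None,
    recorder: Optional[Callable[[PopulationState], None]] = None,
) -> PopulationState:
    """Grow generation-by-generation until total >= capacity, truncated to capacity.

    Growth stops at the first generation where the total reaches capacity;
    the overshoot is truncated proportionally across genotypes.
    """
    rng = _as_rng(rng)
    if state.total == 0:
        return state
    if max_generations is None:
        max_generations = int(math.ceil(math.log2(max(capacity / state.total, 2.0)))) * 4 + 8
    gens = 0
    while state.total < capacity and gens < max_generations:
        state = grow_one_generation(state, mut, rng, deterministic=deterministic)
        gens += 1
        if recorder is not None:
            recorder(state)
    return _truncate_to(state, capacity)


def run_host_cycle(
    state: PopulationState,
    scheme: PassageScheme,
    mut: MutationParams = NO_MUTATION,
    rng=None,
    *,
    recorder: Optional[Callable[[PopulationState], None]] = None,
) -> PopulationState:
    """One day in the light organ: regrow to carrying capacity, then vent.

    An extinct input state is returned unchanged (extinction is an outcome,
    not an error).
    """
    rng = _as_rng(rng)
    if state.total == 0:
        return state
    growth_states: List[PopulationState] = []
    state = grow_to_capacity(
        state, scheme.carrying_capacity, mut, rng,
        recorder=growth_states.append if recorder is not None else None,
    )
    if scheme.venting_survival_fraction < 1.0:
        state = apply_fractional_bottleneck(state, scheme.venting_survival_fraction, rng)
    if recorder is not None:
        # record intermediate growth generations, then the end-of-day (post-
        # vent) state; the capacity-reaching generation is reported post-vent
        # so each generation appears exactly once in the trajectory
        for st in growth_states[:-1]:
            recorder(st)
        recorder(state)
    return state


@dataclass
class Trajectory:
    """Lineage-resolved record of one passage series."""

    records: List[tuple]  # (passage, cycle, generation, genotype_id, s, count)
    status: str
    fates: Dict[int, str]
    genotypes: Dict[int, Genotype]
    final_state: Optional[PopulationState] = None
    seed_info: str = ""

    COLUMNS = ("passage", "cycle", "generation", "genotype_id", "s", "count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=list(self.COLUMNS))


def run_passage_series(
    scheme: PassageScheme,
    mut: MutationParams = NO_MUTATION,
    rng=None,
    *,
    record: bool = True,
) -> Trajectory:
    """Full series: inoculum expansion, then recruitment + daily cycles per host.

    The ventate of each host seeds the next host's recruitment bottleneck.
    If the population cannot found the next host the series ends early with
    the extinction recorded in ``status``.
    """
    rng = _as_rng(rng)
    records: List[tuple] = []

    def snap(passage: int, cycle: int, st: PopulationState) -> None:
        if not record:
            return
        for gid in sorted(st.counts):
            n = st.counts[gid]
            if n > 0:
                records.append((passage, cycle, st.generation, gid, st.genotypes[gid].s, n))

    state = founding_state(scheme.n0)
    snap(0, 0, state)
    guard = int(math.ceil(math.log2(scheme.n_inoc / scheme.n0))) * 4 + 8
    gens = 0
    while state.total < scheme.n_inoc and gens < guard:
        state = grow_one_generation(state, mut, rng)
        gens += 1
        snap(0, 0, state)

    status = "completed"
    for host in range(1, scheme.n_hosts + 1):
        if state.total < scheme.recruitment_size:
            status = f"extinct_at_passage_{host}"
            break
        state = apply_fixed_bottleneck(state, scheme.recruitment_size, rng)
        state = replace(state, phase="host")
        snap(host, 0, state)
        extinct = False
        for cycle in range(1, scheme.cycles_per_host + 1):
            rec = (lambda st, h=host, c=cycle: snap(h, c, st)) if record else None
            state = run_host_cycle(state, scheme, mut, rng, recorder=rec)
            if state.total == 0:
                status = f"extinct_at_passage_{host}"
                extinct = True
                break
        if extinct:
            break

    fates = {}
    freqs = state.frequencies()
    for gid in state.genotypes:
        f = freqs.get(gid, 0.0)
        fates[gid] = "extinct" if f == 0.0 else ("fixed" if f == 1.0 else "segregating")
    return Trajectory(records, status, fates, dict(state.genotypes), state)


@dataclass
class MutantFateResult:
    """Monte-Carlo estimate of a single mutant lineage's survival probability."""

    frequency: float
    ci_low: float
    ci_high: float
    replicates: int
    survivors: int
    unresolved: int = 0
    confidence_level: float = 0.95


def mutant_fate_monte_carlo(
    t: int,
    s: float,
    regime: BottleneckRegime | int,
    replicates: int,
    rng=None,
    *,
    dilution: Optional[float] = None,
    cycles: Optional[int] = None,
    establishment_threshold: int = 500,
    max_cycles: int = 100,
    confidence_level: float = 0.95,
) -> MutantFateResult:
    """Fate of a single mutant cell arising at generation ``t`` of growth.

    The resident population grows deterministically; the focal lineage is a
    branching process: per generation each mutant cell leaves ``2**(1+s)``
    offspring in expectation (fraction realized by a Poisson draw), and each
    bottleneck is a binomial thinning with survival probability ``dilution``
    (default ``2**-tau``, which returns the population to its pre-growth size).

    With ``cycles=None`` (default) each replicate runs until the lineage is
    extinct or reaches ``establishment_threshold`` cells immediately after a
    bottleneck, at which point stochastic loss is no longer credible; the
    returned frequency estimates the establishment probability compared by the
    analytic approximation. With integer ``cycles`` the lineage is propagated
    through exactly that many bottlenecks and survival means a non-zero count.

    Returns the survival frequency with an exact Clopper-Pearson interval.
    """
    tau = _tau_of(regime)
    if int(t) != t or not 1 <= t <= tau:
        raise DomainError(f"t must satisfy 1 <= t <= tau={tau}, got {t!r}")
    if s < 0:
        raise DomainError("selection coefficient must be >= 0")
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    t = int(t)
    rng = _as_rng(rng)
    D = 2.0 ** (-tau) if dilution is None else float(dilution)
    if not 0.0 < D <= 1.0:
        raise DomainError("dilution must lie in (0, 1]")

    f = 2.0 ** (1.0 + s)
    base = math.floor(f)
    frac = f - base

    n = np.ones(replicates, dtype=float)
    active = np.ones(replicates, dtype=bool)
    survived = np.zeros(replicates, dtype=bool)

    def grow(idx: np.ndarray) -> None:
        ni = n[idx]
        small = ni < 1e6
        out = np.empty_like(ni)
        if small.any():
            ns = ni[small].astype(np.int64)
            extra = rng.poisson(ns * frac) if frac > 0 else 0
            out[small] = ns * base + extra
        if (~small).any():
            out[~small] = ni[~small] * f  # deterministic above hybrid threshold
        n[idx] = out

    # Partial first cycle: the mutant arises during generation t, then grows
    # for the remaining tau - t generations before the bottleneck.
    for _ in range(tau - t):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        grow(idx)

    n_bottlenecks = max_cycles if cycles is None else cycles
    for _ in range(n_bottlenecks):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        ni = n[idx]
        post = np.empty_like(ni)
        big = ni > 4e18
        if (~big).any():
            post[~big] = rng.binomial(ni[~big].astype(np.int64), D)
        if big.any():
            lam = ni[big] * D
            post[big] = np.where(lam > 1e6, lam, rng.poisson(np.minimum(lam, 1e6)))
        n[idx] = post
        if cycles is None:
            established = active & (n >= establishment_threshold)
            survived |= established
            active &= ~established
        active &= n > 0
        if not active.any():
            break
        idx = np.flatnonzero(active)
        for _ in range(tau):
            grow(idx)
            idx = idx[n[idx] > 0]
            if idx.size == 0:
                break
        active &= n > 0

    unresolved = int(active.sum()) if cycles is None else 0
    survived |= active & (n > 0)

    k = int(survived.sum())
    ci = stats.binomtest(k, replicates).proportion_ci(
        confidence_level=confidence_level, method="exact"
    )
    return MutantFateResult(
        frequency=k / replicates,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        replicates=replicates,
        survivors=k,
        unresolved=unresolved,
        confidence_level=confidence_level,
    )
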