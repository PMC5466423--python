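"""Synthetic competition and passage data with known ground truth.

Emulates the raw data of a squid co-colonization competition: each host
recruits ~12 founder cells by multivariate-hypergeometric sampling from an
inoculum containing an evolved genotype (selection coefficient ``s_true``,
simulator scale) at a known frequency; the founders grow to the light-organ
carrying capacity (24 hr sample) and optionally through one vent/regrow cycle
(48 hr sample); both markers are recovered by dilution plating with Poisson
counting noise and a ~15 CFU detection floor.

Two start-abundance reference modes control what the emitted observation
reports as the inoculum:

* ``"inoculum"`` (default, paper-realistic): the observation carries the true
  inoculum density (CFU/mL) and evolved frequency. The fitness estimator's
  scale is then contaminated by the recruitment dilution and capacity
  truncation, exactly as in the real experiment.
* ``"founder"``: the observation reports the realized founder abundances as
  the start. With deterministic growth and exact plating this makes the
  estimator identity ``s_estimated = s_true / ln 2`` exact, so it is the mode
  for calibration and parameter-recovery tests.

``noiseless=True`` switches every stochastic step to its expectation
(fractional founder counts, fixed-generation deterministic growth with no
capacity truncation, exact plating); the result is the generator's analytic
backbone and the target for bias measurements on noisy cohorts
(:func:`expected_estimator_s`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DomainError, UsageError
from .fitness import (
    DETECTION_FLOOR_CFU,
    CompetitionObservation,
    estimate_selection,
)
from .simulate import (
    Genotype,
    MutationParams,
    PassageScheme,
    PopulationState,
    _as_rng,
    apply_fractional_bottleneck,
    grow_to_capacity,
    run_passage_series,
)
from .survival import LN2

__all__ = [
    "CompetitionGeneratorConfig",
    "PlateCount",
    "plate_counts",
    "draw_founder_counts",
    "generate_competition_experiment",
    "expected_estimator_s",
    "calibrate_s_true",
    "generate_passage_dataset",
]

EVOLVED_ID = 1


@dataclass(frozen=True)
class CompetitionGeneratorConfig:
    """Study conditions for one synthetic competition cohort.

    Defaults mirror the in-vivo competition: 98 hosts at 24 hr and 59 at
    48 hr, inoculum densities 1,600-26,600 CFU/mL, evolved frequencies from
    1e-4 to 0.5 (log-uniform), 12-cell founders, 5e5-cell organ capacity, 95%
    venting, whole-homogenate plating with a 15-CFU detection floor. The
    default ``s_true`` (~1.1 x ln 2 on the simulator scale) emulates the
    selective advantage reported at 24 hr.
    """

    s_true: float = 1.1 * LN2
    hosts_per_timepoint: Dict[int, int] = field(
        default_factory=lambda: {24: 98, 48: 59}
    )
    density_range: Tuple[float, float] = (1600.0, 26600.0)
    frequency_range: Tuple[float, float] = (1e-4, 0.5)
    founder_size: int = 12
    carrying_capacity: int = 500_000
    venting_survival_fraction: float = 0.05
    plating_dilution: float = 1.0
    detection_floor: float = DETECTION_FLOOR_CFU
    reference: str = "inoculum"
    noiseless: bool = False
    inoculum_pool: int = 10_000_000
    overdispersion: Optional[float] = None  # negative-binomial shape; None = Poisson

    def __post_init__(self) -> None:
        lo_d, hi_d = self.density_range
        lo_f, hi_f = self.frequency_range
        if lo_d <= 0 or hi_d < lo_d:
            raise DomainError("density_range must be positive and ordered")
        if not (0.0 < lo_f <= hi_f < 1.0):
            raise DomainError("frequency_range must lie in (0, 1) and be ordered")
        if self.founder_size < 1:
            raise DomainError("founder_size must be >= 1")
        if self.founder_size > self.carrying_capacity:
            raise UsageError("founder_size exceeds carrying_capacity")
        if not 0.0 < self.venting_survival_fraction < 1.0:
            raise DomainError("venting_survival_fraction must lie in (0, 1)")
        if self.plating_dilution <= 0:
            raise DomainError("plating_dilution must be > 0")
        if self.reference not in ("inoculum", "founder"):
            raise UsageError(f"unknown reference mode {self.reference!r}")
        if any(tp not in (24, 48) for tp in self.hosts_per_timepoint):
            raise UsageError("timepoints must be 24 or 48 hr")


@dataclass(frozen=True)
class PlateCount:
    count: int
    below_detection: bool


def plate_counts(
    true_abundance: float,
    dilution_factor: float,
    detection_floor: float,
    rng=None,
    *,
    overdispersion: Optional[float] = None,
) -> PlateCount:
    """Colony count from dilution-plating an abundance: Poisson(abundance/dilution).

    The implied abundance (count x dilution) below ``detection_floor`` is
    flagged below-detection. An optional negative-binomial shape parameter
    adds overdispersion (real plate counts overdisperse); default is Poisson.
    """
    if true_abundance < 0:
        raise DomainError("true abundance must be >= 0")
    if dilution_factor <= 0:
        raise DomainError("dilution factor must be > 0")
    rng = _as_rng(rng)
    lam = true_abundance / dilution_factor
    if lam == 0:
        count = 0
    elif overdispersion is None:
        count = int(rng.poisson(lam))
    else:
        k = float(overdispersion)
        count = int(rng.negative_binomial(k, k / (k + lam)))
    return PlateCount(count, count * dilution_factor < detection_floor)


def draw_founder_counts(
    frequency: float, founder_size: int, rng=None, *, pool: int = 10_000_000
) -> Tuple[int, int]:
    """(evolved, ancestor) founder cells: hypergeometric draw from the inoculum."""
    if not 0.0 < frequency < 1.0:
        raise DomainError("frequency must lie in (0, 1)")
    rng = _as_rng(rng)
    evolved_pool = max(int(round(frequency * pool)), 1)
    colors = np.array([evolved_pool, pool - evolved_pool], dtype=np.int64)
    draw = rng.multivariate_hypergeometric(colors, founder_size)
    return int(draw[0]), int(draw[1])


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _grow_deterministic(
    counts: np.ndarray, s: np.ndarray, capacity: int, *, fixed_generations: Optional[int]
) -> Tuple[np.ndarray, int]:
    """Float-exact deterministic growth.

    With ``fixed_generations`` set, grows exactly that many generations with no
    capacity truncation (the noiseless, exact-recovery mode). Otherwise grows
    until the total reaches capacity and rescales the overshoot proportionally.
    """
    factors = 2.0 ** (1.0 + s)
    counts = counts.astype(float).copy()
    if fixed_generations is not None:
        counts *= factors**fixed_generations
        return counts, fixed_generations
    gens = 0
    guard = int(math.ceil(math.log2(capacity))) * 4 + 8
    while counts.sum() < capacity and gens < guard:
        counts *= factors
        gens += 1
    total = counts.sum()
    if total > capacity:
        counts *= capacity / total
    return counts, gens


def _grow_stochastic(
    founders: Tuple[int, int], s_true: float, config: CompetitionGeneratorConfig,
    timepoint: int, rng: np.random.Generator,
) -> Tuple[float, float, int]:
    """Stochastic growth of one host's population; returns (end_evo, end_anc, gens)."""
    genotypes = {
        0: Genotype(0, 0.0, None, 0),
        EVOLVED_ID: Genotype(EVOLVED_ID, s_true, 0, 0),
    }
    counts = {}
    if founders[1] > 0:
        counts[0] = founders[1]
    if founders[0] > 0:
        counts[EVOLVED_ID] = founders[0]
    state = PopulationState(counts, genotypes, 0, "host")
    state = grow_to_capacity(state, config.carrying_capacity, rng=rng)
    if timepoint == 48:
        state = apply_fractional_bottleneck(
            state, config.venting_survival_fraction, rng
        )
        state = grow_to_capacity(state, config.carrying_capacity, rng=rng)
    return (
        float(state.counts.get(EVOLVED_ID, 0)),
        float(state.counts.get(0, 0)),
        state.generation,
    )


def _noiseless_host(
    config: CompetitionGeneratorConfig, timepoint: int, frequency: float
) -> Tuple[np.ndarray, int]:
    """Expectation pipeline for one host; returns (end abundances, generations)."""
    founders = np.array(
        [
            config.founder_size * frequency,
            config.founder_size * (1.0 - frequency),
        ]
    )
    s = np.array([config.s_true, 0.0])
    fixed = (
        int(math.floor(math.log2(config.carrying_capacity / config.founder_size)))
        if config.noiseless
        else None
    )
    counts, gens = _grow_deterministic(
        founders, s, config.carrying_capacity, fixed_generations=fixed
    )
    if timepoint == 48:
        counts = counts * config.venting_survival_fraction
        if config.noiseless:
            regrow = int(math.floor(math.log2(1.0 / config.venting_survival_fraction)))
            counts2, g2 = _grow_deterministic(
                counts, s, config.carrying_capacity, fixed_generations=regrow
            )
        else:
            counts2, g2 = _grow_deterministic(
                counts, s, config.carrying_capacity, fixed_generations=None
            )
        counts, gens = counts2, gens + g2
    return counts, gens


def generate_competition_experiment(
    config: CompetitionGeneratorConfig, rng=None
) -> Tuple[List[CompetitionObservation], pd.DataFrame]:
    """One synthetic cohort: observations plus the hidden ground-truth table.

    Hosts whose founder draw contains zero evolved cells are retained (as in
    the real rare-variant inoculations); their evolved colony count is zero
    and the estimator censors them at the detection floor.
    """
    rng = _as_rng(rng)
    observations: List[CompetitionObservation] = []
    truth_rows = []
    for timepoint in sorted(config.hosts_per_timepoint):
        for i in range(config.hosts_per_timepoint[timepoint]):
            host_id = f"t{timepoint}_h{i:03d}"
            density = _log_uniform(rng, *config.density_range)
            frequency = _log_uniform(rng, *config.frequency_range)

            if config.noiseless:
                ends, gens = _noiseless_host(config, timepoint, frequency)
                end_evo, end_anc = float(ends[0]), float(ends[1])
                founder_evo = config.founder_size * frequency
                founder_anc = config.founder_size - founder_evo
                count_evo = end_evo / config.plating_dilution
                count_anc = end_anc / config.plating_dilution
            else:
                founder_evo, founder_anc = draw_founder_counts(
                    frequency, config.founder_size, rng, pool=config.inoculum_pool
                )
                end_evo, end_anc, gens = _grow_stochastic(
                    (founder_evo, founder_anc), config.s_true, config, timepoint, rng
                )
                count_evo = plate_counts(
                    end_evo, config.plating_dilution, config.detection_floor, rng,
                    overdispersion=config.overdispersion,
                ).count
                count_anc = plate_counts(
                    end_anc, config.plating_dilution, config.detection_floor, rng,
                    overdispersion=config.overdispersion,
                ).count

            if config.reference == "founder":
                obs_density = float(config.founder_size)
                total = founder_evo + founder_anc
                obs_freq = founder_evo / total if founder_evo > 0 else frequency
                obs_freq = min(max(obs_freq, 1e-12), 1.0 - 1e-12)
            else:
                obs_density = density
                obs_freq = frequency

            observations.append(
                CompetitionObservation(
                    host_id=host_id,
                    timepoint_hr=timepoint,
                    count_evolved=count_evo,
                    count_ancestor=count_anc,
                    dilution_factor=config.plating_dilution,
                    inoculum_density=obs_density,
                    inoculum_frequency_evolved=obs_freq,
                )
            )
            truth_rows.append(
                {
                    "host_id": host_id,
                    "timepoint_hr": timepoint,
                    "true_density": density,
                    "true_frequency": frequency,
                    "founder_evolved": founder_evo,
                    "founder_ancestor": founder_anc,
                    "end_evolved": end_evo,
                    "end_ancestor": end_anc,
                    "generations": gens,
                    "s_true": config.s_true,
                    "reference": config.reference,
                }
            )
    return observations, pd.DataFrame(truth_rows)


def expected_estimator_s(
    config: CompetitionGeneratorConfig,
    timepoint: int = 24,
    *,
    frequency: Optional[float] = None,
    density: Optional[float] = None,
) -> float:
    """Estimator-scale s for the deterministic expectation of one host.

    Runs the generator's expectation pipeline (proportional founders,
    deterministic growth with capacity truncation unless ``noiseless``) and
    feeds the result through :func:`bottlepass.fitness.estimate_selection`.
    This is the structural target that noisy-cohort means are compared with:
    it carries the same bookkeeping scale factors (recruitment dilution,
    capacity truncation, vent/regrow) as the estimator itself.
    """
    lo_f, hi_f = config.frequency_range
    lo_d, hi_d = config.density_range
    frequency = math.sqrt(lo_f * hi_f) if frequency is None else frequency
    density = math.sqrt(lo_d * hi_d) if density is None else density
    ends, _ = _noiseless_host(config, timepoint, frequency)
    if config.reference == "founder":
        obs_density, obs_freq = float(config.founder_size), frequency
    else:
        obs_density, obs_freq = density, frequency
    obs = CompetitionObservation(
        host_id="expectation",
        timepoint_hr=timepoint,
        count_evolved=float(ends[0]) / config.plating_dilution,
        count_ancestor=float(ends[1]) / config.plating_dilution,
        dilution_factor=config.plating_dilution,
        inoculum_density=obs_density,
        inoculum_frequency_evolved=obs_freq,
    )
    return estimate_selection(obs, detection_floor=0.0).s


def calibrate_s_true(
    target_estimator_s: float,
    config: CompetitionGeneratorConfig,
    timepoint: int = 24,
    *,
    max_s: float = 8.0,
) -> float:
    """Simulator-scale s_true whose deterministic expectation hits a target
    estimator-scale selection coefficient under ``config``.

    The bracket is expanded upward from the naive guess ``target * ln 2``
    until the expectation crosses the target; at very large s the estimator's
    scale is no longer monotone (the ancestor's Malthusian parameter changes
    sign), so calibration is restricted to coefficients below ``max_s``.
    """

    def gap(s_sim: float) -> float:
        return (
            expected_estimator_s(replace(config, s_true=s_sim), timepoint)
            - target_estimator_s
        )

    lo = 1e-8
    hi = max(target_estimator_s * LN2, 0.1)
    while gap(hi) < 0.0:
        hi *= 1.5
        if hi > max_s:
            raise DomainError(
                f"cannot calibrate: target {target_estimator_s} not reachable "
                f"with s_true <= {max_s} under this configuration"
            )
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def generate_passage_dataset(
    scheme: PassageScheme,
    mut: MutationParams,
    n_lineages: int,
    rng=None,
    *,
    detectable_frequency: float = 0.05,
) -> pd.DataFrame:
    """Per-lineage outcomes of independent passage series.

    Each lineage is one full serial-passage experiment; the output records
    whether it survived all passages, the passage at which it went extinct
    otherwise, and whether any non-ancestral variant was detected (frequency
    at least ``detectable_frequency`` in the final population) or fixed.
    """
    if n_lineages < 1:
        raise DomainError("n_lineages must be >= 1")
    rng = _as_rng(rng)
    rows = []
    for lineage in range(n_lineages):
        traj = run_passage_series(scheme, mut, rng, record=False)
        final = traj.final_state
        freqs = final.frequencies() if final is not None else {}
        variant_freq = sum(f for gid, f in freqs.items() if gid != 0)
        extinct_at = None
        if traj.status.startswith("extinct_at_passage_"):
            extinct_at = int(traj.status.rsplit("_", 1)[1])
        rows.append(
            {
                "lineage": lineage,
                "status": traj.status,
                "extinct_at_passage": extinct_at,
                "n_genotypes_seen": len(traj.genotypes),
                "variant_frequency_final": variant_freq,
                "variant_detected": variant_freq >= detectable_frequency,
                "variant_fixed": any(
                    fate == "fixed" for gid, fate in traj.fates.items() if gid != 0
                ),
                "final_total": final.total if final is not None else 0,
            }
        )
    return pd.DataFrame(rows)
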