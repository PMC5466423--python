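"""Selection-coefficient inference from marked-strain competition counts.

A co-inoculated host is homogenized and dilution-plated; blue and white colony
counts of the two marked competitors, together with the inoculum density and
composition, yield per-strain Malthusian parameters

    M = ln(end abundance / start abundance)

the relative growth-rate difference ``s_GR = (M_evo - M_anc) / M_anc``, and
the selection coefficient on the estimator scale ``s = s_GR / ln 2``. The
selection rate between two competitors is the difference of their Malthusian
parameters, ``r = M_focal - M_reference``.

The estimator scale differs from the simulator (doubling-exponent) scale used
by :mod:`bottlepass.simulate`; with both strains measured over the same number
of generations and founder-referenced start abundances the scales are related
by exactly a factor of ln 2, and :func:`estimator_to_simulator` /
:func:`simulator_to_estimator` convert between them.

Hypothesis testing follows the study's practice: exact Fisher-Pitman
permutation tests (difference of group means over all assignments of the
pooled values), with a seeded Monte-Carlo fallback above an enumeration cap,
and the exact binomial test for convergence patterns.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UsageError

LN2 = math.log(2.0)

#: Minimum abundance recoverable by dilution plating of a light-organ homogenate.
DETECTION_FLOOR_CFU = 15.0

__all__ = [
    "DETECTION_FLOOR_CFU",
    "CompetitionObservation",
    "FitnessEstimate",
    "TestResult",
    "TimepointSummary",
    "FrequencyDiagnostic",
    "ExperimentSummary",
    "malthusian",
    "estimate_selection",
    "selection_rate",
    "estimator_to_simulator",
    "simulator_to_estimator",
    "fisher_pitman_test",
    "exact_binomial_test",
    "convergence_null_probability",
    "summarize_experiment",
]


@dataclass(frozen=True)
class CompetitionObservation:
    """One co-colonized host: paired colony counts plus inoculum composition.

    ``count_evolved`` / ``count_ancestor`` are recovered colony counts (real-
    valued to admit noiseless synthetic data); end abundances are counts times
    ``dilution_factor``. Start abundances are ``inoculum_density`` times the
    per-strain inoculum frequency.
    """

    host_id: str
    timepoint_hr: int
    count_evolved: float
    count_ancestor: float
    dilution_factor: float
    inoculum_density: float
    inoculum_frequency_evolved: float
    marker_orientation: str = "evolved_blue"

    def __post_init__(self) -> None:
        if self.count_evolved < 0 or self.count_ancestor < 0:
            raise DomainError(f"host {self.host_id}: colony counts must be >= 0")
        if not 0.0 < self.inoculum_frequency_evolved < 1.0:
            raise DomainError(
                f"host {self.host_id}: inoculum frequency must lie in (0, 1)"
            )
        if self.inoculum_density <= 0:
            raise DomainError(f"host {self.host_id}: inoculum density must be > 0")
        if self.dilution_factor <= 0:
            raise DomainError(f"host {self.host_id}: dilution factor must be > 0")


@dataclass
class FitnessEstimate:
    """Malthusian parameters of both competitors and the derived coefficients."""

    host_id: str
    timepoint_hr: int
    m_evolved: float
    m_ancestor: float
    s_gr: float
    s: float
    censored_evolved: bool = False
    censored_ancestor: bool = False
    valid: bool = True
    note: str = ""

    @property
    def censored(self) -> bool:
        return self.censored_evolved or self.censored_ancestor


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    alternative: str = "two_sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError("p-value outside [0, 1]")


def malthusian(n_end: float, n_start: float) -> float:
    """Malthusian parameter M = ln(n_end / n_start); negative for decline."""
    if n_end <= 0 or n_start <= 0:
        raise DomainError(
            f"Malthusian parameter undefined for non-positive abundances "
            f"(n_end={n_end!r}, n_start={n_start!r})"
        )
    return math.log(n_end / n_start)


def selection_rate(m_focal: float, m_reference: float) -> float:
    """Selection rate r = M_focal - M_reference (natural-log units)."""
    return m_focal - m_reference


def estimator_to_simulator(s_estimator: float) -> float:
    """Convert estimator-scale s (= s_GR / ln 2) to the simulator doubling scale."""
    return s_estimator * LN2


def simulator_to_estimator(s_simulator: float) -> float:
    """Convert simulator-scale s to the estimator scale (divide by ln 2)."""
    return s_simulator / LN2


def estimate_selection(
    obs: CompetitionObservation, detection_floor: float = DETECTION_FLOOR_CFU
) -> FitnessEstimate:
    """Per-host Malthusian parameters, s_GR, and s = s_GR / ln 2.

    A competitor recovered with zero colonies is censored at the plating
    detection floor (its end abundance is set to ``detection_floor`` and the
    estimate flagged) rather than dropped, preserving rare-variant hosts.
    An estimate with M_ancestor = 0 is flagged invalid (s_GR undefined).
    """
    start_evo = obs.inoculum_density * obs.inoculum_frequency_evolved
    start_anc = obs.inoculum_density * (1.0 - obs.inoculum_frequency_evolved)

    end_evo = obs.count_evolved * obs.dilution_factor
    end_anc = obs.count_ancestor * obs.dilution_factor
    cens_evo = end_evo < detection_floor
    cens_anc = end_anc < detection_floor
    if cens_evo:
        end_evo = detection_floor
    if cens_anc:
        end_anc = detection_floor

    m_evo = malthusian(end_evo, start_evo)
    m_anc = malthusian(end_anc, start_anc)
    if m_anc == 0.0:
        return FitnessEstimate(
            obs.host_id, obs.timepoint_hr, m_evo, m_anc, math.nan, math.nan,
            cens_evo, cens_anc, valid=False, note="M_ancestor = 0; s_GR undefined",
        )
    s_gr = (m_evo - m_anc) / m_anc
    return FitnessEstimate(
        obs.host_id, obs.timepoint_hr, m_evo, m_anc, s_gr, s_gr / LN2,
        cens_evo, cens_anc, valid=True,
        note="censored at detection floor" if (cens_evo or cens_anc) else "",
    )


# ---------------------------------------------------------------------------
# Resampling tests


def _tail_count(stats_arr: np.ndarray, observed: float, alternative: str, tol: float) -> int:
    if alternative == "two_sided":
        return int(np.count_nonzero(np.abs(stats_arr) >= abs(observed) - tol))
    if alternative == "greater":
        return int(np.count_nonzero(stats_arr >= observed - tol))
    if alternative == "less":
        return int(np.count_nonzero(stats_arr <= observed + tol))
    raise UsageError(f"unknown alternative {alternative!r}")


def fisher_pitman_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two_sided",
    mode: str = "exact",
    rng=None,
    *,
    max_exact: int = 10**6,
    n_resamples: int = 10**5,
) -> TestResult:
    """Fisher-Pitman permutation test on the difference of group means.

    Exact mode enumerates every assignment of the pooled values to groups of
    the observed sizes; the p-value is the proportion of assignments whose
    statistic is as or more extreme than the observed one (two-sided: absolute
    value; ties count as extreme). If the number of assignments exceeds
    ``max_exact`` the test falls back to Monte-Carlo sampling with a warning;
    Monte-Carlo p-values include the observed assignment in numerator and
    denominator.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise UsageError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = a.mean() - b.mean()
    scale = max(np.ptp(pooled), 1.0)
    tol = 1e-12 * scale

    if mode == "exact" and math.comb(n, na) > max_exact:
        warnings.warn(
            f"C({n},{na}) = {math.comb(n, na)} exceeds the exact cap {max_exact}; "
            "falling back to Monte-Carlo",
            stacklevel=2,
        )
        mode = "monte_carlo"

    if mode == "exact":
        total = math.comb(n, na)
        pooled_sum = pooled.sum()
        # mean_a - mean_b is affine in sum_a: enumerate sums over index subsets
        coef = 1.0 / na + 1.0 / (n - na)
        stats_arr = np.fromiter(
            (sum(c) for c in itertools.combinations(pooled, na)),
            dtype=float,
            count=total,
        )
        stats_arr = stats_arr * coef - pooled_sum / (n - na)
        extreme = _tail_count(stats_arr, observed, alternative, tol)
        return TestResult(
            observed, extreme / total, f"exact ({total} assignments)", alternative
        )

    if mode != "monte_carlo":
        raise UsageError(f"unknown mode {mode!r}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    perms = rng.permuted(np.tile(pooled, (n_resamples, 1)), axis=1)
    stats_arr = perms[:, :na].mean(axis=1) - perms[:, na:].mean(axis=1)
    extreme = _tail_count(stats_arr, observed, alternative, tol)
    p = (1 + extreme) / (1 + n_resamples)
    return TestResult(
        observed, p, f"monte_carlo ({n_resamples} resamples)", alternative
    )


_SCIPY_ALT = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def exact_binomial_test(
    k: int, n: int, p0: float, alternative: str = "two_sided"
) -> TestResult:
    """Exact binomial test; two-sided p by the small-p-values (minlike) method."""
    if not 0 <= k <= n or n < 1:
        raise DomainError(f"require 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise DomainError(f"null probability must lie in (0, 1), got {p0!r}")
    if alternative not in _SCIPY_ALT:
        raise UsageError(f"unknown alternative {alternative!r}")
    res = stats.binomtest(k, n, p0, alternative=_SCIPY_ALT[alternative])
    return TestResult(float(k), float(res.pvalue), f"exact binomial (n={n})", alternative)


def convergence_null_probability(n_strains: int = 4, p_each: float = 0.5) -> float:
    """Null probability that all assayed strains show one of the two convergent
    response patterns by chance: ``2 * p_each**n_strains`` (12.5% for four
    strains at p=0.5)."""
    if n_strains < 1:
        raise DomainError("n_strains must be >= 1")
    return 2.0 * p_each**n_strains


# ---------------------------------------------------------------------------
# Experiment-level summary


@dataclass
class TimepointSummary:
    timepoint_hr: int
    n_valid: int
    mean_s: float
    ci_low: float
    ci_high: float
    degenerate_ci: bool = False


@dataclass
class FrequencyDiagnostic:
    """OLS of estimated s on log10(inoculum frequency): hard-selection check."""

    slope: float
    slope_ci_low: float
    slope_ci_high: float
    intercept: float
    n: int
    covers_zero: bool


@dataclass
class ExperimentSummary:
    estimates: pd.DataFrame
    timepoints: dict = field(default_factory=dict)
    comparison: Optional[TestResult] = None
    frequency_diagnostic: Optional[FrequencyDiagnostic] = None
    missing_timepoints: list = field(default_factory=list)


def _bootstrap_mean_ci(
    values: np.ndarray, n_resamples: int, rng: np.random.Generator
) -> tuple:
    """Bias-corrected (BCa) percentile bootstrap CI for the mean."""
    if values.size < 2 or np.allclose(values, values[0]):
        return float(values[0]), float(values[0]), True
    try:
        res = stats.bootstrap(
            (values,),
            np.mean,
            n_resamples=n_resamples,
            method="BCa",
            random_state=rng,
            vectorized=True,
            axis=-1,
        )
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
        if math.isnan(lo) or math.isnan(hi):
            raise ValueError("degenerate BCa interval")
        return lo, hi, False
    except Exception:
        lo, hi = np.percentile(values, [2.5, 97.5])
        return float(lo), float(hi), True


def summarize_experiment(
    observations: Sequence[CompetitionObservation],
    *,
    detection_floor: float = DETECTION_FLOOR_CFU,
    include_censored: bool = False,
    bootstrap_resamples: int = 10_000,
    rng=None,
) -> ExperimentSummary:
    """Per-host estimates, per-timepoint mean s with 95% CI, and group tests.

    Censored estimates (a competitor below the detection floor) are carried in
    the per-host table but excluded from means, the between-timepoint test and
    the frequency diagnostic unless ``include_censored`` is set. The frequency
    diagnostic regresses s on log10(inoculum frequency); under hard selection
    the slope's 95% CI covers zero.
    """
    if not observations:
        raise UsageError("need at least one observation")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    rows = []
    for obs in observations:
        est = estimate_selection(obs, detection_floor)
        rows.append(
            {
                "host_id": est.host_id,
                "timepoint_hr": est.timepoint_hr,
                "m_evolved": est.m_evolved,
                "m_ancestor": est.m_ancestor,
                "s_gr": est.s_gr,
                "s": est.s,
                "censored": est.censored,
                "valid": est.valid,
                "inoculum_frequency_evolved": obs.inoculum_frequency_evolved,
                "inoculum_density": obs.inoculum_density,
            }
        )
    table = pd.DataFrame(rows)

    usable = table[table["valid"] & (include_censored | ~table["censored"])]
    timepoints: dict = {}
    missing = []
    for tp, grp in table.groupby("timepoint_hr"):
        vals = usable.loc[usable["timepoint_hr"] == tp, "s"].to_numpy()
        if vals.size == 0:
            missing.append(int(tp))
            continue
        if vals.size == 1:
            timepoints[int(tp)] = TimepointSummary(
                int(tp), 1, float(vals[0]), float(vals[0]), float(vals[0]), True
            )
            continue
        lo, hi, degen = _bootstrap_mean_ci(vals, bootstrap_resamples, rng)
        timepoints[int(tp)] = TimepointSummary(
            int(tp), vals.size, float(vals.mean()), lo, hi, degen
        )

    comparison = None
    tps = sorted(timepoints)
    if len(tps) == 2:
        s_a = usable.loc[usable["timepoint_hr"] == tps[0], "s"].to_numpy()
        s_b = usable.loc[usable["timepoint_hr"] == tps[1], "s"].to_numpy()
        mode = "exact" if math.comb(s_a.size + s_b.size, s_a.size) <= 10**6 else "monte_carlo"
        comparison = fisher_pitman_test(s_a, s_b, mode=mode, rng=rng)

    diagnostic = None
    diag = usable[np.isfinite(usable["s"])]
    if len(diag) >= 3 and diag["inoculum_frequency_evolved"].nunique() >= 2:
        x = np.log10(diag["inoculum_frequency_evolved"].to_numpy())
        y = diag["s"].to_numpy()
        fit = stats.linregress(x, y)
        half = stats.t.ppf(0.975, len(diag) - 2) * fit.stderr
        lo, hi = fit.slope - half, fit.slope + half
        diagnostic = FrequencyDiagnostic(
            float(fit.slope), float(lo), float(hi), float(fit.intercept),
            len(diag), bool(lo <= 0.0 <= hi),
        )

    return ExperimentSummary(table, timepoints, comparison, diagnostic, missing)
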