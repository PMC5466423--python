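"""Mutation supply at a focal locus during clonal population expansion.

Under binary fission, a population of N0 cells reaches ``N0 * 2**g`` cells
after ``g`` generations, having undergone ``N0 * (2**g - 1)`` cell divisions
(each division adds one cell). With a per-base-pair, per-division mutation
rate ``mu`` and a target of ``locus_length_bp * nonsyn_fraction`` mutable
positions, the expected number of focal mutations produced during the
expansion is

    lambda = mu * locus_length_bp * nonsyn_fraction * divisions

and the Poisson probability that at least one arises is ``1 - exp(-lambda)``.
All parameters are explicit inputs; the study's parameter table ships as a
named default configuration in :mod:`bottlepass.study`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "MutationSupplyParams",
    "cumulative_divisions",
    "generations_to_size",
    "expected_locus_mutations",
    "prob_at_least_one",
    "supply_report",
]


@dataclass(frozen=True)
class MutationSupplyParams:
    """Inputs for the locus mutation-supply calculation."""

    mu: float  # per-bp per-cell-division mutation rate
    locus_length_bp: int
    nonsyn_fraction: float
    n0: int  # starting cells
    n_final: float  # final cells

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise DomainError("mu must be >= 0")
        if self.locus_length_bp < 1:
            raise DomainError("locus_length_bp must be >= 1")
        if not 0.0 < self.nonsyn_fraction <= 1.0:
            raise DomainError("nonsyn_fraction must lie in (0, 1]")
        if self.n0 < 1 or self.n_final <= self.n0:
            raise DomainError("require n_final > n0 >= 1")

    @property
    def target_bp(self) -> float:
        return self.locus_length_bp * self.nonsyn_fraction


def cumulative_divisions(n0: int, g: int) -> int:
    """Cell divisions in ``g`` doubling generations starting from ``n0`` cells.

    Equals ``n0 * (2**g - 1)``: each of the n0 founding lineages contributes a
    complete binary tree of depth g, and a tree with ``2**g`` leaves has
    ``2**g - 1`` internal division events.
    """
    if g < 0 or int(g) != g:
        raise DomainError(f"generations must be a non-negative integer, got {g!r}")
    if n0 < 1:
        raise DomainError("n0 must be >= 1")
    return int(n0) * (2 ** int(g) - 1)


def generations_to_size(n0: float, n_final: float) -> float:
    """Doubling generations to grow from ``n0`` to ``n_final``: log2(N_final/N0).

    Fractional; callers report ``math.floor`` for a whole-generation count.
    """
    if n0 < 1:
        raise DomainError("n0 must be >= 1")
    if n_final < n0:
        raise DomainError(f"n_final must be >= n0, got {n_final} < {n0}")
    return math.log2(n_final / n0)


def expected_locus_mutations(params: MutationSupplyParams, divisions: float) -> float:
    """Expected focal-locus mutations lambda over the given number of divisions."""
    if divisions < 0:
        raise DomainError("divisions must be >= 0")
    return params.mu * params.target_bp * divisions


def prob_at_least_one(lam: float) -> float:
    """Poisson probability of at least one mutation: 1 - exp(-lambda)."""
    if lam < 0:
        raise DomainError("lambda must be >= 0")
    return -math.expm1(-lam)


def supply_report(params: MutationSupplyParams, first_g: int | None = None) -> dict:
    """Summary of the mutation supply implied by ``params``.

    If ``first_g`` is given, also reports the supply restricted to the first
    ``first_g`` generations of the expansion. Divisions over the complete
    expansion are ``n_final - n0`` (each division adds one cell).
    """
    gens = generations_to_size(params.n0, params.n_final)
    divisions_total = params.n_final - params.n0
    lam_total = expected_locus_mutations(params, divisions_total)
    report = {
        "generations": gens,
        "generations_floor": math.floor(gens),
        "divisions_total": divisions_total,
        "lambda_total": lam_total,
        "p_at_least_one_total": prob_at_least_one(lam_total),
    }
    if first_g is not None:
        div_first = cumulative_divisions(params.n0, first_g)
        lam_first = expected_locus_mutations(params, div_first)
        report.update(
            {
                "first_g": first_g,
                "divisions_first_g": div_first,
                "lambda_first_g": lam_first,
                "p_at_least_one_first_g": prob_at_least_one(lam_first),
            }
        )
    return report
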