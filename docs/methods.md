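# Methods

`bottlepass` models the population genetics of a bacterial symbiont passing
through host-imposed growth/bottleneck cycles — the regime experienced by
*Vibrio fischeri* colonizing the squid light organ — and infers selection
coefficients from marked-strain competition counts. This note records the
models, conventions, numerical choices, and limitations.

## The passage model

One passage cycle consists of:

1. **Inoculum expansion.** N₀ cells (default 5) grow by binary fission to
   N_inoc (default 2.4×10⁸), i.e. log₂(N_inoc/N₀) ≈ 25.5 generations.
2. **Recruitment bottleneck.** Each host light organ is founded by a fixed
   number of cells (default 12, configurable; published estimates range from
   ~10 to 12) drawn without replacement — a multivariate hypergeometric sample
   across genotypes.
3. **Within-host growth.** The founders regrow to the light-organ carrying
   capacity (default 5×10⁵ cells). Growth stops at the first generation where
   the total reaches capacity; overshoot is truncated proportionally across
   genotypes (largest-remainder rounding). No within-host density-regulation
   model beyond this hard cap is attempted.
4. **Venting.** At dawn ~95% of the population is expelled: each cell
   survives independently with probability 0.05 (binomial thinning). Venting
   is applied after growth reaches capacity; whether venting precedes or
   follows the day's final division is not observable in the source data, so
   the simpler convention was fixed.
5. **Serial transfer.** After the configured number of daily cycles (default
   4) the ventate founds the next host's recruitment bottleneck; default 15
   hosts in series. If all lineages die out the series ends early with the
   extinction recorded as an outcome, not an exception.

**Fitness convention (simulator scale).** A genotype with coefficient *s*
multiplies by 2^(1+s) per generation while the ancestor doubles. Fractional
expected offspring are realized by a Poisson draw on the fractional part, so
a neutral lineage doubles exactly and growth noise for weakly selected
lineages is small — consistent with binary fission, in which the dominant
stochasticity is bottleneck sampling, not reproduction.

**Mutation.** New mutants arise as Poisson(μ_locus × divisions) per
generation, where the division count is the net cell increase (each division
adds one cell; a population growing from N₀ through g doublings accumulates
N₀(2^g − 1) divisions). Each mutant founds a one-cell lineage with a
configurable coefficient; the mutant daughter replaces one parental daughter
so cell number is conserved.

**Hybrid updating.** Genotypes at ≥1000 cells update deterministically
(rounded expectation); smaller lineages remain fully stochastic. This keeps
full runs (2.4×10⁸ cells, thousands of lineages) at sub-second cost while
rare-lineage drift — the quantity of scientific interest — is simulated
exactly. The threshold is a keyword argument in spirit: it is a module
constant (`STOCHASTIC_CUTOFF`) chosen so that binomial noise at the threshold
(relative SD < 3%) is negligible against the bottleneck noise that dominates.

**Determinism.** All randomness flows through one `numpy.random.Generator`;
identical seeds give bit-identical trajectories, and the CLI records the seed
in every output's metadata header.

## Analytic survival approximation

For a beneficial mutant arising during generation *t* of a growth phase with
τ generations between bottlenecks, the first-order (in *s*) survival
probability is

    π(t, s) = s · τ · ln 2 / 2^(t−1),    V = 1 − π

clamped to [0, 1] (the raw value is available via `clamp=False`). The two
regimes shipped as defaults are τ = 25 (recruitment after inoculum growth)
and τ = 4 (daily venting). The printed source expression is typographically
garbled; this transcription is the cited first-order result, reproduces the
"<10% survival at s≈2, t=10" statement (π = 0.0677), and is the only reading
in which survival increases with *s*.

**Validity domain.** The formula linearises two quantities: the mutant's
excess growth before its first bottleneck (a factor 2^{s(τ−t)} ≈ 1) and the
per-lineage establishment probability (2·ln m with m = 2^{sτ} ≈ 1). Both
require s·τ ≲ 1. The Monte-Carlo cross-check (`mutant_fate_monte_carlo`, an
exact branching process: near-deterministic fission growth, binomial
bottleneck thinning with survival 2^{−τ}, run to establishment at 500 cells
or extinction) agrees with the formula within ±30% for s·τ ≤ 0.5 and raw
π ≤ 0.2, and the tests pin agreement at four such points. Outside that
domain the formula can be badly conservative: at (t=10, s=2, τ=25) it gives
π = 0.068 while the exact branching process survives essentially always
(the mutant grows 2^{3·15} ≈ 10¹³-fold before the bottleneck). Users reading
the survival surface at large s·τ should treat it as the source model's
approximation, not as the branching-process truth; the simulator is the
reference for that regime.

## Mutation supply

λ = μ × locus_bp × nonsyn_fraction × divisions, with P(≥1) = 1 − e^{−λ}.
Divisions are counted as cell-count increase (≈ N_final − N₀ for a full
expansion), matching the simulator's accounting. With the study's own
parameter table (μ = 2.08×10⁻⁸ bp⁻¹division⁻¹, 2595 bp × 2/3, 5 → 2.4×10⁸
cells) the implied supply is λ ≈ 8.6×10³ locus mutations per inoculum
expansion and λ ≈ 0.18 within the first 10 generations. These disagree with
the published totals ("~325", "185", and a 0.004 first-10-generation
probability), which are mutually inconsistent and not recoverable from the
printed inputs; the module reports what the inputs imply and asserts nothing
about the printed values.

## Selection-coefficient estimation

Per co-colonized host, with end abundances = colony count × dilution factor
and start abundances = inoculum density × per-strain frequency:

    M = ln(end / start)          (Malthusian parameter, per strain)
    s_GR = (M_evo − M_anc)/M_anc
    s = s_GR / ln 2              (estimator scale)
    r = M_focal − M_reference    (selection rate)

**Zero counts** are censored at the plating detection floor (default 15 CFU)
and flagged, rather than dropped — dropping them would bias cohorts toward
hosts where both strains happened to be recovered. M_anc = 0 makes s_GR
undefined; such estimates are flagged invalid. Marker orientation is carried
through unmodified so users can test for plasmid/marker artifacts; no
correction is applied.

**Scale relations.** With both strains competing over the same g generations
and founder-referenced starts, M_anc = g·ln 2 exactly, so s_GR equals the
simulator-scale coefficient and s = s_sim/ln 2; `estimator_to_simulator` /
`simulator_to_estimator` convert by the factor ln 2. With inoculum-referenced
starts (the realistic bookkeeping) M_anc additionally contains the
recruitment dilution and capacity truncation, so the estimator's scale is
structurally contaminated — this is a property of the estimator itself, not
of the implementation, and it is why single-host estimates can be extreme
when M_anc is near zero. The published worked selection rate illustrates the
hazard: the printed inputs ln(1/325) and ln(9/2.4×10⁸) give r ≈ 11.3, not
the printed 5.6; the package implements the printed formula and documents the
discrepancy without asserting either number.

**Summaries.** Per-timepoint mean s carries a bias-corrected (BCa) bootstrap
95% CI (default 10,000 seeded resamples; the CI method is a package choice —
the source reports CIs without naming one). Timepoints are compared with the
exact Fisher-Pitman permutation test: statistic = difference of group means,
p = fraction of all C(n, n_a) assignments at least as extreme (two-sided:
absolute value; ties count as extreme, matching the exact-distribution
behaviour of the standard implementation). Above a configurable enumeration
cap (10⁶ assignments) the test falls back to seeded Monte-Carlo with the
observed assignment included in numerator and denominator. The exact binomial
test (minlike two-sided) covers convergence-pattern nulls such as
2 × 0.5⁴ = 12.5% for four strains.

**Hard-selection diagnostic.** The experiment summary regresses estimated s
on log₁₀(inoculum frequency) (OLS, 95% slope CI). Under hard selection —
fitness advantage independent of starting frequency, which is how the
simulator is constructed — the CI covers zero; the tests verify this at the
study's conditions (98 hosts, densities 1,600–26,600 CFU/mL, frequencies
10⁻⁴–0.5).

## Synthetic-data generator

The generator emulates the in-vivo competition: per host it draws an inoculum
density and evolved frequency (log-uniform over the study's ranges), samples
12 founders hypergeometrically, grows them to capacity with the evolved
genotype at `s_true` (24 hr), optionally applies one vent/regrow cycle
(48 hr; the 24↔48 hr mapping to one venting cycle of ~4 generations is a
package choice, configurable), and plates both markers with Poisson counting
noise (an optional negative-binomial knob models the overdispersion of real
plate counts) against the 15-CFU floor. Hosts with zero evolved founders are
retained, as in the real rare-variant inoculations. Default cohort sizes
(98 at 24 hr, 59 at 48 hr) and s_true ≈ 1.1·ln 2 mirror the study.

Two start-abundance reference modes:

* `"inoculum"` — observations carry the true density and frequency; the
  estimator inherits the realistic structural scale contamination described
  above.
* `"founder"` — observations reference the realized founder abundances; in
  the noiseless limit the identity s = s_true/ln 2 is exact, which the tests
  verify to <10⁻⁹ relative error.

`expected_estimator_s` runs the generator's deterministic expectation
(proportional founders, deterministic growth, capacity truncation) through
the estimator; it is the target against which noisy-cohort bias is measured
(<10% at n = 50 hosts for s_true ∈ {0.5, 1, 2}), and `calibrate_s_true`
inverts it by bracketed root-finding (restricted to s ≤ 8, beyond which the
estimator's scale is non-monotone because M_anc changes sign).

**What the generator does not emulate:** crypt substructure (one well-mixed
population per host, as in the source model), host sanctioning, marker
(plasmid) fitness effects, sequencing, luminescence, and between-experiment
block effects. Passing recovery tests therefore demonstrates estimator
correctness under the stated sampling model, not robustness to these real
phenomena.

## Problem sizes and tolerances

Stochastic tests use fixed seeds and 3-SE acceptance bands around exact
expectations; Monte-Carlo sizes (10⁴–10⁵ replicates) were chosen so those
bands are decisive, and the whole suite runs in well under a minute.
Permutation-test calibration uses 2,000 null replicates of 6-vs-6 groups
(924 assignments each, vectorized); the discrete exact test's rejection rate
at α = 0.05 is 46/924 ≈ 0.0498 in expectation and is required to fall in
[0.035, 0.065]. Root-finding tolerances are 10⁻¹⁰ (calibration); float
round-tripping through TSV uses `%.17g` on write and round-trip parsing on
read.

## Known limitations

* The survival approximation is first-order in s (see above); the package
  deliberately exposes both it and the exact simulator rather than a
  diffusion or exact branching-process fixation formula.
* The estimator's inoculum-referenced scale mixes units (CFU/mL inoculum vs
  CFU/organ recovery), as in the source protocol; cross-study comparison of
  absolute s values on that scale is hazardous.
* Deterministic updating above 1000 cells ignores reproduction noise in
  large lineages; their drift is then driven entirely by bottlenecks, which
  is the correct leading-order behaviour but omits O(1/√N) growth noise.
* The carrying-capacity truncation is proportional (deterministic); a
  stochastic final generation would add small extra drift near capacity.
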