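# Methods

`cytomaint` couples two models: a continuous-time Markov chain (CTMC)
availability model of redundant repairable preparation-hood systems, and a
triangular-fuzzy-number TOPSIS group-decision model that ranks maintenance
alternatives, followed by a criteria-weight sensitivity analysis.  This note
records the models, their assumptions, the numerical conventions, and the
design choices made where the design was genuinely open.

## Availability model

A hood is a series arrangement of sections (filter, gas extraction,
control/alarms) with constant per-hour failure rates λ_j and repair rates
μ_j; failures and repairs are exponential.  The series arrangement collapses
to equivalent rates

    λ_eq = Σ_j λ_j,          μ_eq = λ_eq / Σ_j (λ_j / μ_j),

the second being the failure-frequency-weighted combination that preserves
the series unavailability λ_eq/μ_eq = Σ λ_j/μ_j.  A system of n identical
hoods is a birth–death CTMC on states 0..n (number of failed hoods) with:

* **load sharing (hot standby):** all working hoods are active and share the
  workload equally, so the aggregate failure rate from state i is
  (n − i)·λ_eq;
* **one repair crew:** every repair transition has rate μ_eq, not i·μ_eq;
* **failure only when all hoods are down:** operational states are 0..n−1;
* **preventive windows are not downtime:** scheduled maintenance is
  programmed work and is not represented in the chain.

The stationary vector solves p·A = (0,…,0,1) where A is the generator with
its last column replaced by ones (the normalisation Σp = 1 replacing one
redundant balance equation); mean availability D_m is the stationary mass on
the operational states.  Chains here have at most a handful of states, so a
dense direct solve is used and a singular matrix raises rather than falling
back to least squares.  Closed forms are provided for one unit
(D = μ/(λ+μ), equivalently 1/(1+Σλ_j/μ_j), identical to the equivalent-rate
route to 1e−12 by construction) and for the two-state transient
D(t) = μ/(λ+μ) + λ/(λ+μ)·e^{−(λ+μ)t}.

Policy variants are expressed through `active_sections`: a policy that
prevents failures of a section (e.g. outsourced thermographic predictive
maintenance of the filter) removes that section from the failure pool before
the rates are collapsed.

Availabilities are reported rounded to 4 decimal places; internal values are
never rounded.  Steady-state vectors are validated to sum to 1 within 1e−12
with nonnegative components.

## Fuzzy TOPSIS model

Judgements are triangular fuzzy numbers (l, m, u), l ≤ m ≤ u, manipulated
with the standard componentwise operational laws (product and quotient are
the usual vertex approximations, valid for nonnegative support; the
constructors re-validate ordering so misuse fails loudly).  Two seven-level
linguistic scales are packaged: weights on [0, 1] (VL … VH) and ratings on
[0, 10] (VP … VG).  An expert may judge with a single label, an explicit
triple, or a label interval; intervals span the lower label's l to the upper
label's u, with the modal value fixed by a `combine_rule`:

* `MEAN_OF_MODALS` (default): modal = mean of the two labels' modals;
* `MIDPOINT_OF_SUPPORT`: modal = midpoint of the combined support;
* `AS_GIVEN`: the judgement carries its own modal.

An interval judgement that records its own modal is always resolved as
given, whatever rule is in force: a recorded group consensus takes
precedence over any recombination convention.  This matters because real
consensus groups do not apply one mechanical rule — the packaged case study
contains intervals whose modals follow the mean-of-modals convention, the
midpoint convention, and neither — and silently reinterpreting recorded
judgements would change published results.

The pipeline aggregates the K decision makers' resolved TFNs by the
componentwise mean, normalises, weights, and ranks:

1. **Normalisation** (`NormalisationMode`):
   * `GLOBAL_MAX` (default): every column divided by its largest upper
     bound u⁺_j, identically for benefit and cost criteria; cost direction
     is handled entirely by the ideal profiles.
   * `SCALE_MAX`: every entry divided by the rating scale's fixed upper
     bound (10 for the packaged scale).  This is the fictional-alternative
     construction — a virtual best alternative at the scale maximum and a
     virtual worst at zero — whose denominator cannot depend on which
     alternatives are present.
   * `COST_INVERSE`: benefit columns as GLOBAL_MAX; cost columns inverted
     through the column's smallest lower bound l⁻_j as
     (l⁻_j/u, l⁻_j/m, l⁻_j/l), rejecting zero components.
2. **Weighting:** v_ij = r_ij ⊗ w_j componentwise.
3. **Ideals** (`IdealConvention`): `ABSOLUTE` (default) uses fixed crisp
   profiles — benefit criteria aim at (1,1,1) and away from (0,0,0), cost
   criteria the reverse; `CHEN` uses the weighted matrix's per-column
   extremes.
4. **Separations:** d±_i = Σ_j d_v(v_ij, ideal_j) with the vertex distance
   d_v(a,b) = sqrt(((l_a−l_b)² + (m_a−m_b)² + (u_a−u_b)²)/3), a metric on
   the vertex space normalised so d_v((0,0,0),(1,1,1)) = 1.
5. **Closeness and ranking:** CC_i = d⁻_i/(d⁻_i + d⁺_i), ranked decreasing;
   ties are broken lexicographically by alternative name and logged.

### Rank reversal

With ABSOLUTE ideals the reference profiles never move, but under
GLOBAL_MAX the normalisation denominators still depend on the alternative
set.  An empirical check (400 random problems, one alternative added to
each) found pairwise order reversals among pre-existing alternatives *only*
when the new alternative raised a column's maximum upper bound (24 of 2400
pairs; zero reversals when every column maximum was unchanged).  Full
insensitivity to alternative addition/removal therefore requires the
data-independent denominator, i.e. `SCALE_MAX`; the property tests assert
unconditional order preservation under SCALE_MAX and conditional
preservation (unchanged column maxima) under GLOBAL_MAX.  GLOBAL_MAX
remains the default because it reproduces the published case-study tables;
on that fixture the two modes coincide, since every criterion column
attains the scale maximum u = 10.

### Sensitivity analysis

Each scenario scales one criterion's aggregated fuzzy weight componentwise
by (1 + δ), δ ∈ {−20%, −10%, +10%, +20%}, clips components to [0, 1] (the
weight scale's range; clipping events are logged), and reruns the pipeline
with the other weights untouched.  No renormalisation is applied — fuzzy
TOPSIS imposes no sum-to-one constraint on weights, and perturbing one
weight is the stated procedure.  All three TFN components are scaled
(perturbing only the modal would leave the support, which dominates the
vertex distance, untouched).  The model is reported `stable` when every
scenario reproduces the baseline ranking.

## Synthetic data and the stochastic oracle

The problem generator draws weight and rating judgements uniformly from the
packaged scales, replacing a judgement with an adjacent-label interval with
configurable probability (adjacent only: that is the only interval form
consensus groups use on these scales).  Defaults mirror the case study's
shape: 4 alternatives × 6 criteria (2 cost), one consensus decision maker,
interval probability 0.3.  The system generator draws section rates
log-uniformly, by default λ ∈ [1e−5, 1e−3] and μ ∈ [1e−2, 1e−1] per hour —
the repairable regime where faults are rare relative to repairs, matching
the order of magnitude of recorded hospital rates.  All generators are
deterministic given their seed, with per-generator random streams.

`simulate_availability` is an event-driven Monte-Carlo simulation of the
same birth–death chain (exponential holding times, rates exactly as the
analytic model), discarding a 10% burn-in and averaging the operational
fraction over replicates.  It is the independent stochastic oracle for the
steady-state solver: across 50 random systems the analytic value falls
within 3 standard errors of the simulated estimate in at least 95% of
cases (tested at horizon 2×10⁵ h, 12 replicates — long enough for tens of
failure/repair cycles per replicate while keeping the whole suite fast).

What the generators do *not* emulate: correlated judgements across criteria
or makers, non-exponential repair distributions, section-level dependence,
and rate uncertainty.  Passing tests demonstrate correctness of the
algebra, the solvers and the pipeline plumbing under the stated model
assumptions, not the adequacy of those assumptions for any particular
hospital's data.

## Numerical conventions and degenerate inputs

* Doubles throughout; test comparisons at absolute tolerance 1e−9 unless a
  reporting contract applies (availabilities 4 d.p.; matrices, distances
  and CC 3 d.p.).
* Degenerate TFN spikes (l = m = u) behave as crisp numbers; membership of
  a spike is the indicator of equality, and half-degenerate sides return
  the limiting membership 1 at the shared point.
* TFN division/inversion require strictly positive divisor support;
  scaling requires k > 0; mixed-sign products are rejected by
  re-validation.
* A judgement interval must be ordered low-to-high on its scale; an
  explicit modal must lie within the combined support.
* `closeness` raises when d⁺ + d⁻ = 0 (single-point degenerate problem).
* The equivalent repair rate is undefined (raises) when every active
  section has zero failure rate; the simulator short-circuits such systems
  to availability exactly 1.

## Known limitations

* Only plain triangular fuzzy numbers; no type-2, intuitionistic or
  hesitant variants, and no defuzzification beyond what TOPSIS needs.
* No semi-Markov or non-exponential repair models; no transient solution
  beyond the two-state closed form; no cost-optimal preventive-maintenance
  interval optimisation.
* Sensitivity analysis is deterministic weight scaling only; no Monte-Carlo
  weight sampling or criteria addition/removal scenarios.
* No other MCDM methods (AHP, PROMETHEE, VIKOR, …) and no weight
  elicitation beyond direct linguistic assignment.
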