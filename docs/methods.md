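# Methods

## Model

A `BayesNet` is a directed acyclic graph over finitely-valued variables,
each with a conditional probability table (CPT); rows must sum to 1 within
1e-9, and internal probability comparisons use 1e-12.  Inference is exact
enumeration: for a binary query *Y* and evidence *e*, every joint
configuration xᵢ of the remaining (hidden) variables contributes a term
p(y, e, xᵢ), and the posterior is the normalised sum.  Query variables must
be binary; hidden and evidence variables may have any arity.  Hidden
configurations are enumerated lexicographically in (variable declaration
order, state declaration order), which fixes the phase index i of every
interference term across runs.  Zero-probability configurations are kept
as terms: they carry zero interference, but they count toward the
configuration number M that sets the interference normalisation 2/(M−1).

The quantum-like layer replaces the hidden-variable sum by a sum of
amplitudes √tᵢ·e^{iθᵢ}, built from the *evidence-conditioned* terms
tᵢ = p(y,e,xᵢ)/p(e).  Conditioning first means a balanced wave is a
posterior directly (the 1/p(e) factor multiplies every term uniformly, so
it commutes with the squared magnitude); at orthogonal phases the wave
collapses exactly to the classical posterior.  The intensity wave is

    I(y, θ₁…θ_M) = Σtᵢ + 2/(M−1) Σ_{i<j} √(tᵢtⱼ) cos(θᵢ−θⱼ).

The 2/(M−1) factor is applied for every M ≥ 2; at M = 2 it equals 2, the
familiar two-slit form, so no special case exists.  Intensity waves are
non-negative but can exceed 1 (the two-slit toy with t₁ = t₂ = 0.5 reaches
2.0 at aligned phases).

## The law of balance

Complementary outcome waves are balanced when their interference cancels
pair by pair: √(tᵢtⱼ)cos(θᵢ−θⱼ) = −√(t′ᵢt′ⱼ)cos(θ′ᵢ−θ′ⱼ) for each of the
λ = M(M−1)/2 pairs, each solvable independently.  Per pair, the
coefficient ratio r decides dominance: the smaller-coefficient wave's
phase is free and determines the counterpart via arccos(−r·cosδ); the
dominating wave's cosine is confined to [−1/r, 1/r].  At r = 1 (within
1e-12 — the equality is exact in doubly stochastic tables and essentially
never arises from data, so a tight tolerance is right) neither dominates
and the counterpart phase is the π-shift, reproducing the unitary-like
transform of doubly stochastic models.  Pairs whose two coefficients both
vanish impose no constraint and contribute nothing.  A global dominance
label is only meaningful at M = 2; for larger M the case is recorded per
pair.

## Attainable intervals

Because balanced waves sum to one, the two intervals mirror each other:
I_large = [1−hi, 1−lo] of the smaller-base wave.  The smaller-base wave is
the one optimised:

* **M = 2 closed form.**  Half-width h = min(2√(t₁t₂), 2√(t′₁t′₂)) — the
  wave's own full interference amplitude, capped by the counterpart's when
  the wave itself dominates.  The interval [base−h, base+h] never leaves
  [0, 2·base] ⊆ [0, 1] by the AM–GM inequality, so clipping is a formality.
  The half-width is the *full* amplitude 2√(t₁t₂): this is what the wave
  formula actually carries, and it reproduces every published interval at
  two decimals, whereas a half-amplitude √(t₁t₂) does not.
* **M ≥ 3 numerically.**  Deterministic min/max of the wave over the M−1
  gauge-fixed phase differences (θ_M = 0): a fixed 64-points-per-axis grid
  (reduced automatically above ~2M evaluations for large M), followed by
  Nelder-Mead refinement from the best grid point (xatol 1e-10, fatol
  1e-13).  Feasibility is enforced by clamping each pair's cosine to its
  ±1/r band, a continuous surrogate for the arccos-domain constraint.  No
  randomness anywhere; identical inputs give identical intervals.  The
  interval is generally asymmetric about the base because the pairwise
  phase differences are coupled (δ₀₂ = δ₀₁ + δ₁₂).

## The law of maximum uncertainty

Dispatch is a function of interval overlap only (closed intervals; shared
endpoints count as overlap):

* **Entropy principle** (disjoint): each wave takes its interval endpoint
  nearest 0.5, the maximum-entropy value that stays inside the attainable
  range.  For M = 2 the two choices are exact complements; for M ≥ 3 each
  wave takes its own endpoint and the (tiny) complementarity defect is
  recorded on the prediction rather than hidden.
* **Mirror principle** (overlapping): the larger-base outcome receives the
  smaller wave's attained positive interference (2√(t₁t₂) at M = 2; the
  numeric maximum minus the base at M ≥ 3 — an extrapolation, flagged here
  because no multi-configuration overlap case has a published reference).
  The smaller outcome takes the complement.
* **Tie p(y) = p(¬y)** (within 1e-12): both intervals centre on 0.5 and
  overlap, and the first-named outcome receives the counterpart wave's
  amplitude — the explicit equal-distribution prescription.  For two-node
  networks the two amplitudes coincide at a tie, so the convention is
  observable only in asymmetric multi-evidence cases.

The quarter-law baseline subtracts a fixed 0.25 from the classical value
and clips to [0, 1]; it models the disjunction-effect direction
(attenuation of the modelled alternative) with no adaptation to the data.

## Replication fixtures and conventions

The bundled CSVs transcribe the published response rates of five
Prisoner's Dilemma experiments (modelled outcome: defection) and four
Two-Stage Gamble experiments (modelled outcome: playing).  Each row is
encoded as a two-node network X → Y with a uniform prior p(x) = 0.5 for
the no-information condition — the natural maximum-ignorance encoding,
and the one that reproduces the published classical column exactly.
Observed unknown-condition frequencies are carried for comparison only and
never enter a prediction.

Two table conventions are honoured explicitly rather than silently:

* the *Average* row's classical value is the **mean of the per-row
  classical values** (0.88125 → 0.8813 for the Prisoner's Dilemma), not
  the classical value of the averaged conditionals (0.885) — asserted in
  the tests;
* the Average row's wave is built on that value **pre-rounded to two
  decimals** (base 0.88/0.12), matching the published interval
  [0.77, 0.99] and pq 0.77; all non-average rows use unrounded bases.
  Both modes are available (`qlbn.uncertainty.with_base`).

Table rounding is half-away-from-zero at 2 decimals.  One published pq
cell is printed as "076"; it is stored as the evident 0.76.  The last
Two-Stage-Gamble row is labelled (vi) in one published table and (iv) in
the other; the fixtures use (iv).

## Synthetic-network generator

`random_network(seed, n_vars, max_parents, doubly_stochastic)` emits
seeded binary networks whose structure (each variable choosing parents
among its predecessors) is acyclic by construction and whose CPT rows are
valid by construction; identical seeds give byte-identical serialisations.
It emulates arbitrary small discrete networks for property testing —
enumeration vs. brute-force joint summation, balance cancellation, case-3
detection (the doubly-stochastic chain mode) — and does not attempt to
mimic the statistics of real behavioural data: passing property tests
demonstrates the algebra of the machinery, not predictive validity on new
experiments.

## Numerical and scope notes

* Problem sizes: property tests use networks of up to 6 binary variables
  (full joint ≤ 64 rows) and interval oracles use 4096-point (M = 2) and
  128² (M = 3) phase grids; these sizes make every oracle exhaustive while
  keeping the whole suite a few seconds.
* In the three-configuration worked example the optimiser's maximum is
  0.4746 at aligned phases (Σ√(tᵢtⱼ) = 0.21455 above the base 0.26); one
  published statement of the upper bound reads 0.48, which the wave
  formula with 2/(M−1) = 1 does not attain.  The implementation follows
  the formula; the minimum 0.13 agrees either way.
* Similarly, one published lower bound of 0.20 computes to 0.2098 (→ 0.21)
  in closed form; the discrepancy is noted, not reproduced.
* Approximate inference, continuous variables, structure learning, full
  Hilbert-space state evolution and per-experiment phase fitting are out
  of scope by design; the point of the balance/maximum-uncertainty pair is
  precisely to remove the fitted phase θ*.
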