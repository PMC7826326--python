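# Methods

## Models

All three simulators share a discrete clock: one item is acquired per
integer time step, and an item acquired at step s that is erased at step
e has age e − s at erasure.  Acquisition precedes erasure within a step,
and a new item can never be erased on its own acquisition step (it cannot
dominate itself).

**Full erasure.**  Items carry valence vectors **v** ∈ ℝⁿ with components
i.i.d. from a continuous distribution P(v).  The newcomer erases every
stored item it strictly dominates in all n components.  Because only the
relative ranks of valences matter, retention is distribution-free; the
package nevertheless keeps P(v) configurable (any continuous
scipy.stats distribution) and *rejects* distributions with atoms rather
than inventing tie semantics — strict dominance is almost surely decisive
only for atom-free laws.  Erasure is purely retroactive, so the store is
not an antichain of the dominance order: an old, strong item may well
dominate a younger survivor (for n = 1 the store is exactly a chain, with
valence increasing with age).  The invariant the tests assert is the
correct one-sided version: no stored item is ever dominated by a
*later-acquired* stored item.

**Single erasure.**  Scalar valences; the newcomer erases the stored
minimum iff its own valence exceeds that minimum (reading "the smallest
valence" over the union of store and newcomer).  Store size never
decreases and N(T)/T → 1/e.

**Linear decay.**  The non-interacting reference: strengths a − b·age
with a, b drawn from configurable non-negative-support distributions
(degenerate `constant` values allowed, e.g. b ≡ 0); an item is erased at
the first step where strength ≤ 0, i.e. at age ⌈a/b⌉.  For uniform a and
b on (0, 1), survival at lag τ ≥ 1 is exactly 1/(2τ), matching the
asymptote P_b(0)·⟨a⟩/τ.

## Numerics

- The n-dimensional retention recurrence is evaluated by iterated prefix
  sums, O(n·t_max) time; `retention_nd_at` and `cumulative_retained`
  stream the same recurrence in chunks (default 2²¹ lags) so lags up to
  10⁸ need O(chunk) memory (~2 s on one core).  Double precision is ample:
  the n = 1 base case is computed directly as 1/(t+1) and the summands are
  positive and decreasing.
- All logarithms are natural; the asymptotic exponent −1 + (n−1)/log t is
  consistent with the asymptotic curve logⁿ⁻¹(t+1)/((n−1)!(t+1)) only in
  base e.
- The scalar full-erasure simulator uses a monotone stack (the store,
  acquisition-ordered, has strictly decreasing valences, so victims form
  a suffix found by binary search) — amortised O(T).  The general engine
  keeps the store in a compact array and vectorises the dominance scan;
  the expected store size is ~logⁿT/n!, so total cost is near-linear in T
  for small n.  Both paths are cross-checked against each other and
  against a literal O(T²) rule-application oracle.
- Local exponents and hazards use `numpy.gradient` (central differences
  in log-log or linear space, one-sided at the ends); retention is
  rebuilt from a hazard by trapezoidal quadrature.  These agree with
  closed forms to discretisation error (~1% for curves sampled on integer
  lags near lag 1), which is the tolerance the tests use.
- The empirical retention estimator conditions on acquisition time
  ≤ T − max_lag so every contributing item is observed over the whole
  window (no right-censoring bias); intervals are Wilson binomial CIs
  (statsmodels).  Replicate runs use seed + replicate index; everything
  is reproducible bit-for-bit from (config, seed).
- The large-lag approximation undershoots the exact curve by a factor
  1 − O(1/log t): the relative error at t = 10⁴–10⁶ is still 20–30% for
  n = 5 even though the two curves look superimposed on a log-log plot.
  Tests therefore assert the honest property (ratio in (0.3, 1),
  increasing decade over decade) rather than a small error band.

## Synthetic recognition experiment

The generator emulates a 500-word stream with 75 recognition queries per
participant: 25 two-back, 25 ten-back, 25 on the first 25 words (each of
those queried exactly once, one query falling after the final word).
Design choices, made once:

- **Positions and lags.**  A query at position q occurs after q words;
  its targets are q − 2 / q − 10 for the back conditions and lag = q −
  target.  Under this convention a word queried at lag t has faced
  exactly t subsequent acquisitions, so pipeline accuracies compose
  exactly with the theoretical curves via p(t) = (1 + Rₙ(t))/2.
- **Blocking.**  Consecutive queries are at least lag + 1 positions apart
  for back conditions (so no query intervenes between a back target's
  presentation and its query) and at least 1 apart otherwise; the random
  query points start after position n_early + 10 so back targets never
  collide with the early-word pool, and leftover stream slack is spread
  multinomially over the inter-query gaps.  This sampler is a reasonable
  uniform-ish choice, not a claim about how any particular experiment
  placed its queries.
- **Encoding fatigue.**  Encoding probability 1 − γ·pos/L (default
  γ = 0.3), the simplest monotone decline producing the characteristic
  drop of 2-back accuracy along the stream; a word that is not encoded is
  never stored and elicits a pure guess.
- **Short-term memory.**  Under the interference memory model, 2-back
  targets are recalled whenever encoded (they are still within short-term
  span); 10-back and early targets are retained iff no encoded later word
  dominates them.  The degenerate `always_retained`/`never_retained`
  models override this protection — they are calibration references for
  the ceiling and the 50% guessing floor.
- **Words are opaque.**  Token identities never influence behaviour, so
  the stream and lure words are not materialised; the pool-size check
  (pool ≥ stream + lures) is still enforced.  No response times, word
  frequencies, or participant-level payment/qualification bookkeeping are
  modelled.

## Analysis pipeline

Participants with perfect 2-back accuracy are kept (those with no 2-back
trials are excluded with a warning); trials from the early and 10-back
conditions are pooled, sorted by lag and grouped into equal-population
bins (default population: the number of retained participants; the last
bin may be smaller).  Bin accuracy is inverted through R̂ = 2p − 1,
clipped to [0, 1] for display with the unclipped value kept alongside.
For each candidate dimensionality the predicted accuracy at a bin is
(1 + Rₙ(round(mean lag)))/2 — the exact curve is defined on integer
lags — and the candidate with the smallest RMSE in accuracy space wins,
ties going to the smaller n.  RMSE is this package's scalar criterion
(the underlying comparison in the literature is visual); it is reported
per candidate so other criteria can be swapped in.  Including the
10-back condition adds the single densest lag point (25 trials per
participant at lag 10, where candidate curves differ most), which makes
the selection well-powered at cohorts of 200 participants: across 20
replicates per true n ∈ {1..6}, recovery was 20/20 in every case.

## What the synthetic cohorts do and do not show

Passing recovery tests show that the pipeline is a consistent estimator
of the generating dimensionality *under the generator's own
assumptions* — independent valences, exact guessing behaviour, perfect
binary retention, no item effects, no participant heterogeneity beyond
the encoding model.  They do not validate the interference model against
human data, which involves word-frequency structure, response noise and
strategy effects that the generator deliberately omits.

## Problem sizes

Default desk-scale settings keep every check fast on one core: horizons
of 10⁵–10⁶ steps for simulators (200 replicates of the scalar model run
in ~10 s), exact curves to 10⁶ lags, streamed evaluation for 10⁸, and
cohorts of 120–3000 participants (the full 6 × 20 recovery grid takes
~10 s).

## Known limitations

- Valences are fixed for a memory's lifetime and their distribution is
  stationary; no reinstatement, rehearsal, or time-varying importance.
- The hazard/exponent estimators assume smooth, strictly positive
  curves; they are finite-difference quantities and inherit grid error
  near lag 1.
- The single-erasure and linear-decay variants are scalar-valence only.
- The fatigue model is phenomenological; γ is not calibrated to any
  dataset.
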