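# forgetsim

Valence-gated retroactive-interference models of forgetting: seeded
Monte-Carlo simulators of memory erasure, exact and asymptotic
retention-curve mathematics, and a synthetic delayed-recognition
experiment generator with the accompanying analysis pipeline.

## The scientific problem

Human forgetting is famously well described by power-law retention
curves, R(τ) ∝ τ^(−α): the probability that a memory of age τ is still
available decays slowly, and — counterintuitively — older memories have a
*lower* instantaneous probability of being forgotten (hazard
F(τ) = −R′(τ)/R(τ) ∝ α/τ).  `forgetsim` implements a family of
phenomenological models in which this behaviour emerges from a single
principle: **a newly acquired memory erases previously stored memories
that are less important than it**.

Each memory item carries a valence vector **v** ∈ ℝⁿ of importance
scores, drawn i.i.d. from a continuous distribution (whose form provably
does not matter).  One item is acquired per time step, and

- **full erasure** — the newcomer erases every stored item it strictly
  dominates in *all* n dimensions.  For n = 1, an item survives t steps
  iff it holds the largest of t + 1 exchangeable valences, so

      R₁(t) = 1/(t+1),

  a parameter-free power law.  For n ≥ 2 the retention curve obeys the
  recurrence

      Rₙ(t) = 1/(t+1) · Σ_{k=1..t+1} Rₙ₋₁(k−1),

  with large-t behaviour Rₙ(t) ≈ logⁿ⁻¹(t+1) / ((n−1)!·(t+1)) and a local
  log-log slope α(t) = d log R / d log t ≈ −1 + (n−1)/log t that drifts
  toward −1 only logarithmically (at t = 10⁸ with n = 5 it is still about
  −0.8);
- **single erasure** — the newcomer erases only the stored minimum (if it
  is itself larger); the store then grows linearly, N(T) → T/e;
- **linear decay** — the non-interacting baseline with strength
  S(t) = a − bt and survival R(τ) ≈ P_b(0)·⟨a⟩/τ.

The expected store size Nₙ(T) = Σ_{t≤T} Rₙ(t) separates the variants:
the scalar full-erasure model keeps fewer than twenty memories after
T = 10⁸ acquisitions, while n = 5 keeps tens of thousands — one argument
for a multidimensional notion of importance.

Because erasure is purely retroactive, presenting a fixed item set in any
linear extension of the dominance partial order (dominators first)
protects *every* item — a sharp, testable prediction that separates this
mechanism from passive-decay accounts.

The package also generates synthetic two-alternative forced-choice
recognition experiments (streams of 500 words; 25 two-back, 25 ten-back
and 25 early-word queries per participant; optional encoding fatigue;
guessing at chance when a word is not retained, p(t) = (1 + R(t))/2) and
provides the analysis pipeline — perfect-2-back participant filtering,
equal-population lag binning, guessing correction 2p − 1, and RMSE-based
selection of the valence dimensionality n.

## Worked example

```python
import forgetsim as fs

cfg = fs.ProtocolConfig(n_participants=200,
                        memory=fs.InterferenceMemory(n_dims=5), seed=0)
trials = fs.generate_trials(cfg)
binned, fit = fs.run_recognition_analysis(trials, candidates=range(1, 7))
print(fit.to_dict())
```

which prints (see `examples/recognition_experiment.py` for the full
script):

```
  n=1: rmse = 0.2779
  n=2: rmse = 0.2158
  n=3: rmse = 0.1413
  n=4: rmse = 0.0707
  n=5: rmse = 0.0271  <- selected
  n=6: rmse = 0.0666
```

The cohort was generated with five-dimensional interference; the
pipeline's guessing-corrected accuracies are best matched by the n = 5
theoretical curve, recovering the generating dimensionality.  Other
narrative scripts in `examples/` cover the three simulators against their
closed forms, the exact/asymptotic retention curves and memory counts,
and the presentation-order prediction (a random order of 100
two-dimensional items lost 78 of them; the dominators-first order lost
none).

A thin CLI exposes the same functionality
(`forgetsim simulate|curves|experiment|analyze`, each writing CSV/JSON
outputs plus a reproducibility manifest).

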