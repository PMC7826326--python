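"""A synthetic delayed-recognition cohort, analysed end-to-end.

Generates 200 participants of a 500-word stream protocol (25 two-back, 25
ten-back and 25 early-word recognition queries each) whose memories follow
five-dimensional valence interference, then runs the analysis pipeline:
perfect-2-back filtering, equal-population lag binning, guessing
correction, and dimensionality fitting.
"""

import forgetsim as fs

true_n = 5
cfg = fs.ProtocolConfig(
    n_participants=200,
    memory=fs.InterferenceMemory(n_dims=true_n),
    encoding=fs.PerfectEncoding(),
    seed=0,
)
trials = fs.generate_trials(cfg)
print(f"{len(trials)} trials from {cfg.n_participants} participants")

binned, fit = fs.run_recognition_analysis(trials, candidates=range(1, 7))
print("\nbinned performance (first and last rows):")
cols = ["mean_lag", "n_measurements", "accuracy", "retention_hat"]
print(binned[cols].iloc[[0, 1, -2, -1]].to_string(index=False))

print("\nfit report:")
for n, rmse in zip(fit.candidate_n, fit.rmse):
    marker = "  <- selected" if n == fit.selected_n else ""
    print(f"  n={n}: rmse = {rmse:.4f}{marker}")
print(
    f"\nThe pipeline recovers the generating dimensionality "
    f"(true n = {true_n}, selected n = {fit.selected_n}): accuracy at lag t "
    f"behaves as (1 + R_n(t))/2 once guessing is accounted for."
)
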