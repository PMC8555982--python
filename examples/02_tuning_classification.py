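"""Screen and classify a small synthetic neuron population.

Builds a labeled population (chosen-value, chosen-cost, chosen-juice,
location-only, and untuned cells), screens each response (neuron x window)
for task-relatedness with two 3-way ANOVAs at p < 0.001, then classifies
every task-related response against the 21 candidate decision variables
with the parallel-lines ANCOVA. The best-fit matrix shows, per window, how
many responses each variable fits best — it should concentrate on the
generating signals.
"""

import costchoice as cc
from costchoice import simulate

cfg = cc.SessionConfig(session_id="demo", n_trials=400, seed=11)
recipe = simulate.five_signal_recipe(n_per_class=6, n_untuned=4)
data = simulate.generate_population(recipe, cfg)

result = cc.run_pipeline(data["trials"], data["rates"])

n_related = int(result.screen["task_related"].sum())
print(f"task-related responses: {n_related} of {len(result.screen)}")
print()

best = result.best_fit_matrix
nonzero = best.loc[:, (best != 0).any()]
print("best-fit counts (window x variable), nonzero columns:")
print(nonzero.to_string())
print()
print("each response counts once; the generating variables dominate their windows.")
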