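"""Mutual-information feature selection and a leakage-safe benchmark.

Simulates a labeled feature table in which only two of six features carry
class signal, ranks features by k-NN mutual information against the label,
and runs the 80/20 train-test benchmark with MI selection performed on the
training split only.
"""

import numpy as np
import pandas as pd

from interactor.analysis import mi_rank, run_benchmark, select_top

rng = np.random.default_rng(0)
n = 600
y = pd.Series(rng.choice(["kinase", "protease", "transporter"], size=n))
signal = y.map({"kinase": 0.0, "protease": 3.0, "transporter": 6.0})
X = pd.DataFrame({
    "informative_1": signal + rng.normal(scale=0.5, size=n),
    "informative_2": -signal + rng.normal(scale=1.0, size=n),
    **{f"noise_{i}": rng.normal(size=n) for i in range(4)},
})

ranking = mi_rank(X, y, seed=0)
print("MI scores (nats):")
for name in ranking.order:
    print(f"  {name:<15s} {ranking.scores[name]:.3f}")
print("top 2 selected:", select_top(ranking, 2))

report = run_benchmark(X, y, model_spec="hgb", select_k=2, seed=0)
print(f"\nheld-out metrics (model={report.model}, "
      f"features={report.selected_features}):")
for metric in ("accuracy", "precision", "recall", "f1", "mcc"):
    print(f"  {metric:<10s} {getattr(report, metric):.3f}")

# The two informative features should top the ranking by a wide margin
# and suffice for near-perfect held-out classification; noise features
# score close to 0 nats.
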