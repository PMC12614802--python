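"""Grouped-attribution enrichment: are interaction features doing the work?

Takes a per-protein attribution matrix (e.g. SHAP values from any
explainer), sums attributions within two feature groups per protein, and
compares the two summed distributions per class with a two-sided
two-sample Kolmogorov-Smirnov test, BH-adjusted across classes.  Here the
matrix is synthetic: in class "fam1" the interaction group carries twice
the attribution mass, in "fam2" the groups are exchangeable.
"""

import numpy as np
import pandas as pd

from interactor.analysis import ks_enrichment

rng = np.random.default_rng(1)
n = 80
interaction_cols = [f"int_{i}" for i in range(5)]
other_cols = [f"comp_{i}" for i in range(5)]
matrix = pd.DataFrame(rng.normal(size=(n, 10)),
                      columns=interaction_cols + other_cols)
classes = pd.Series(["fam1"] * (n // 2) + ["fam2"] * (n // 2))
matrix.loc[classes == "fam1", interaction_cols] += 0.8

groups = pd.Series({c: c.startswith("int_") for c in matrix.columns})
result = ks_enrichment(matrix, groups, classes)
print(result.as_frame().to_string(float_format=lambda v: f"{v:.4g}"))

# fam1 should show a large KS statistic and a small adjusted p-value
# (interaction attributions dominate); fam2 should be non-significant.
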