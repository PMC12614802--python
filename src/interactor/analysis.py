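"""Downstream analyses: MI feature ranking, leakage-safe classification
benchmark, and grouped-attribution Kolmogorov-Smirnov enrichment.

The enrichment procedure takes a per-protein, per-feature attribution
matrix (e.g. SHAP values from any explainer), sums attributions within
two feature groups per protein, and compares the two summed samples per
class with a two-sided two-sample KS test, Benjamini-Hochberg-adjusted
across classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (HistGradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import (accuracy_score, f1_score,
                             matthews_corrcoef, precision_score,
                             recall_score)
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MIRanking", "BenchmarkReport", "KSEnrichmentResult",
    "mi_rank", "select_top", "run_benchmark", "ks_enrichment", "bh_adjust",
    "default_models",
]


@dataclass
class MIRanking:
    """Per-feature mutual information (nats) against the class label.

    ``scores`` is indexed by feature name; ``order`` is the ranking,
    highest MI first, ties broken by feature-name lexicographic order.
    """

    scores: pd.Series
    order: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.order:
            tie_broken = sorted(self.scores.items(),
                                key=lambda kv: (-kv[1], kv[0]))
            self.order = [name for name, _ in tie_broken]


@dataclass
class BenchmarkReport:
    model: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    seed: int
    selected_features: list[str]


@dataclass
class KSEnrichmentResult:
    """Per-class KS statistic/p-value for group-A vs group-B summed
    attributions, with BH-adjusted p-values across classes."""

    classes: list[str]
    statistic: np.ndarray
    p_value: np.ndarray
    p_adjusted: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ks_statistic": self.statistic,
                             "p_value": self.p_value,
                             "p_adjusted": self.p_adjusted},
                            index=pd.Index(self.classes, name="class"))


def _as_xy(table, labels):
    """Accept a FeatureTable or an (X, y) pair of DataFrame/Series."""
    if labels is None:
        X, y = table.labeled()
    else:
        X = table.frame if hasattr(table, "frame") else pd.DataFrame(table)
        y = pd.Series(labels, index=X.index) \
            if not isinstance(labels, pd.Series) else labels.loc[X.index]
    if y.nunique() < 2:
        raise ValueError("need at least 2 classes")
    return X, y


def mi_rank(table, labels=None, k_neighbors: int = 3,
            seed: int = 0) -> MIRanking:
    """Rank features by k-NN mutual information with the discrete label.

    Uses the nearest-neighbor MI estimator for continuous features and a
    discrete target (k = ``k_neighbors``), with seeded jitter for distance
    tie-breaking; estimates are clipped at 0.
    """
    X, y = _as_xy(table, labels)
    codes = pd.Categorical(y).codes
    mi = mutual_info_classif(X.to_numpy(), codes,
                             n_neighbors=k_neighbors,
                             discrete_features=False,
                             random_state=seed)
    scores = pd.Series(np.clip(mi, 0.0, None), index=X.columns,
                       name="mi_score")
    return MIRanking(scores=scores)


def select_top(ranking: MIRanking, k: int) -> list[str]:
    """Top-k features by MI score (lexicographic tie-break)."""
    if k > len(ranking.order):
        raise ValueError(f"k={k} exceeds feature count {len(ranking.order)}")
    return ranking.order[:k]


def default_models(seed: int = 0) -> dict[str, object]:
    """The shipped classifier configurations (ensemble tree models)."""
    return {
        "hgb": HistGradientBoostingClassifier(random_state=seed),
        "rf": RandomForestClassifier(n_estimators=200, random_state=seed),
    }


def _stratifiable(y: pd.Series, test_fraction: float) -> bool:
    counts = y.value_counts()
    return counts.min() >= 2 and (counts * test_fraction).min() >= 1


def run_benchmark(table, labels=None, model_spec="hgb",
                  test_fraction: float = 0.2, select_k: int | None = None,
                  seed: int = 0, k_neighbors: int = 3) -> BenchmarkReport:
    """Train/test benchmark with leakage-safe feature selection.

    Shuffles and splits the labeled rows (``test_fraction`` held out),
    optionally MI-selects ``select_k`` features using the training rows
    only, fits the model, and reports accuracy, macro precision/recall/F1
    and MCC on the held-out rows.  If a class is missing from a plain
    shuffled training split, stratified re-splits are attempted before
    giving up.
    """
    X, y = _as_xy(table, labels)
    models = default_models(seed)
    if isinstance(model_spec, str):
        try:
            model = models[model_spec]
            model_name = model_spec
        except KeyError:
            raise ValueError(
                f"unknown model {model_spec!r}; shipped: {sorted(models)}"
            ) from None
    else:
        model = model_spec
        model_name = type(model_spec).__name__

    stratify = y if _stratifiable(y, test_fraction) else None
    for attempt in range(10):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_fraction, random_state=seed + attempt,
            shuffle=True, stratify=stratify)
        if set(y_te) <= set(y_tr):
            break
        stratify = y  # retry stratified
    else:
        raise RuntimeError("could not build a split covering all classes")

    if select_k is not None:
        ranking = mi_rank(X_tr, y_tr, k_neighbors=k_neighbors, seed=seed)
        selected = select_top(ranking, select_k)
    else:
        selected = list(X.columns)
    model.fit(X_tr[selected].to_numpy(), y_tr.to_numpy())
    pred = model.predict(X_te[selected].to_numpy())
    return BenchmarkReport(
        model=model_name,
        accuracy=float(accuracy_score(y_te, pred)),
        precision=float(precision_score(y_te, pred, average="macro",
                                        zero_division=0)),
        recall=float(recall_score(y_te, pred, average="macro",
                                  zero_division=0)),
        f1=float(f1_score(y_te, pred, average="macro", zero_division=0)),
        mcc=float(matthews_corrcoef(y_te, pred)),
        seed=seed,
        selected_features=selected,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ks_enrichment(attribution_matrix: pd.DataFrame, feature_groups,
                  class_partition) -> KSEnrichmentResult:
    """Grouped-attribution enrichment via two-sample KS tests per class.

    ``feature_groups`` flags each column as group A (True, e.g. the
    interaction features) or group B (False, everything else);
    ``class_partition`` assigns each row (protein) to a class.  Per
    class, attributions are summed per protein within each group and the
    two summed samples are compared with a two-sided two-sample KS test;
    p-values are BH-adjusted across classes.
    """
    X = pd.DataFrame(attribution_matrix)
    groups = pd.Series(feature_groups, index=X.columns) \
        if not isinstance(feature_groups, pd.Series) else feature_groups
    groups = groups.reindex(X.columns).astype(bool)
    if groups.sum() == 0 or (~groups).sum() == 0:
        raise ValueError("both feature groups must be non-empty")
    y = pd.Series(class_partition, index=X.index) \
        if not isinstance(class_partition, pd.Series) else class_partition
    sum_a = X.loc[:, groups].sum(axis=1)
    sum_b = X.loc[:, ~groups].sum(axis=1)
    classes = sorted(map(str, y.unique()))
    stats_d, pvals = [], []
    for cls in classes:
        mask = (y.astype(str) == cls).to_numpy()
        res = stats.ks_2samp(sum_a[mask], sum_b[mask],
                             alternative="two-sided")
        stats_d.append(float(res.statistic))
        pvals.append(float(res.pvalue))
    return KSEnrichmentResult(
        classes=classes,
        statistic=np.asarray(stats_d),
        p_value=np.asarray(pvals),
        p_adjusted=bh_adjust(pvals),
    )
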