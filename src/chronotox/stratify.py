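"""K-means patient stratification on clock features.

Features (e.g. BMAL1 acrophase, BMAL1 expression, PER2 MESOR) are z-scored
per column, k-means is run for each candidate k with many restarts, and the
k maximising the mean silhouette width is selected.  A helper cross-tabulates
the chosen clustering against treatment arms with a Fisher exact test and
per-cluster purity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .association import basic_tests

__all__ = ["ClusterResult", "kmeans_stratify", "evaluate_arm_recovery"]


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series  # patient id -> cluster label
    silhouette_mean: float
    centroids: np.ndarray  # in standardized feature space
    per_k: pd.DataFrame  # candidate k -> silhouette, inertia
    features_used: list
    seed: int | None
    n_init: int
    degenerate: bool = False


def kmeans_stratify(
    features: pd.DataFrame,
    k_range=range(2, 7),
    n_init: int = 50,
    seed: int | None = None,
) -> ClusterResult:
    """Standardise features, run k-means over ``k_range``, pick best silhouette.

    Constant feature columns are dropped with a warning.  If every patient is
    identical the silhouette is undefined; the result is returned with
    ``degenerate=True``, k = min(k_range) and all patients in one cluster.
    """
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 for k in ks):
        raise ValueError("k must be >= 2")
    X = features.astype(float)
    if not np.all(np.isfinite(X.to_numpy())):
        raise ValueError("features must be finite")
    keep = [c for c in X.columns if X[c].std(ddof=0) > 0]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping constant feature columns: {dropped}")
    n = X.shape[0]
    if n <= max(ks):
        raise ValueError(f"need more patients ({n}) than the largest k ({max(ks)})")

    if not keep:
        assignments = pd.Series(0, index=features.index, name="cluster")
        return ClusterResult(
            k=ks[0],
            assignments=assignments,
            silhouette_mean=float("nan"),
            centroids=np.zeros((1, 0)),
            per_k=pd.DataFrame({"k": ks, "silhouette": np.nan, "inertia": np.nan}),
            features_used=[],
            seed=seed,
            n_init=n_init,
            degenerate=True,
        )

    Z = (X[keep] - X[keep].mean()) / X[keep].std(ddof=0)
    Zv = Z.to_numpy()

    rows = []
    fits = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(Zv)
        if np.unique(labels).size < 2:
            sil = float("nan")
        else:
            sil = float(silhouette_score(Zv, labels))
        rows.append({"k": k, "silhouette": sil, "inertia": float(km.inertia_)})
        fits[k] = (km, labels, sil)
    per_k = pd.DataFrame(rows)

    if per_k["silhouette"].isna().all():
        k_best = ks[0]
        degenerate = True
    else:
        k_best = int(per_k.loc[per_k["silhouette"].idxmax(), "k"])
        degenerate = False
    km, labels, sil = fits[k_best]
    return ClusterResult(
        k=k_best,
        assignments=pd.Series(labels, index=features.index, name="cluster"),
        silhouette_mean=sil,
        centroids=km.cluster_centers_,
        per_k=per_k,
        features_used=keep,
        seed=seed,
        n_init=n_init,
        degenerate=degenerate,
    )


def evaluate_arm_recovery(result: ClusterResult, arms: pd.Series) -> dict:
    """Cross-tabulate clusters against treatment arms.

    Returns the contingency table, a Fisher exact p-value (2 x k enumeration
    for k > 2 clusters), per-cluster purity and the overall purity (the share
    of patients whose cluster's majority arm matches their own)."""
    arms = arms.reindex(result.assignments.index)
    table = pd.crosstab(arms, result.assignments)
    # Fisher wants a 2 x k layout: arm rows, cluster columns
    if table.shape[0] != 2:
        p = float("nan")
    else:
        _, p = basic_tests(table.to_numpy(), "fisher_exact")
    cluster_purity = {}
    correct = 0
    for cl in table.columns:
        col = table[cl]
        cluster_purity[cl] = float(col.max() / col.sum()) if col.sum() else float("nan")
        correct += int(col.max())
    overall = correct / int(table.to_numpy().sum())
    return {
        "contingency": table,
        "fisher_p": p,
        "cluster_purity": cluster_purity,
        "purity": overall,
    }
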