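"""Patient stratification on module expression: per-sample module scores,
hierarchical endotype clustering, capped group fold changes (GFC),
hypergeometric module annotation, and group-clinical association tests.

Samples are scored per module as the mean cohort-centered log2 expression of
the module's genes; patients (cases only) are then clustered with Ward
agglomerative clustering, picking k by mean silhouette.  Group-level GFCs
are within-group mean scores capped at +/-2, the usual heatmap convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from .coexpression import ModuleSet, NormalizedMatrix
from .diffexp import bh_adjust

__all__ = [
    "EndotypeAssignment",
    "sample_module_scores",
    "EndotypeClusterer",
    "cluster_patients",
    "group_gfc",
    "ora_annotate",
    "hypergeom_tail",
    "associate_clinical",
    "GFC_CAP",
]

GFC_CAP = 2.0


@dataclass
class EndotypeAssignment:
    labels: pd.Series  # sample -> "G1".."Gk"
    k: int
    linkage_matrix: np.ndarray | None
    silhouette_by_k: dict


def sample_module_scores(norm: NormalizedMatrix, modules: ModuleSet) -> pd.DataFrame:
    """Sample x module score matrix.

    score(s, m) = mean over genes g in m of (norm[g, s] - mean_s' norm[g, s']),
    i.e. the per-sample log2 deviation of the module from the cohort mean.
    """
    vals = norm.values
    centered = vals.sub(vals.mean(axis=1), axis=0)
    cols = {}
    for name, genes in modules.modules.items():
        present = [g for g in genes if g in centered.index]
        if not present:
            raise ValueError(f"module {name!r} has no genes in the matrix")
        cols[name] = centered.loc[present].mean(axis=0)
    return pd.DataFrame(cols, index=vals.columns)


class EndotypeClusterer(BaseEstimator, ClusterMixin):
    """Ward agglomerative clustering with silhouette-selected k.

    ``fit(X)`` takes a samples x features matrix (module scores).  k is
    chosen to maximize the mean silhouette over ``k_range`` (ties -> the
    smallest k); clusters are renamed G1..Gk in decreasing-size order
    (ties by first sample id).

    Attributes
    ----------
    labels_ : ndarray of str
    k_ : int
    linkage_matrix_ : scipy linkage matrix
    silhouette_by_k_ : dict k -> mean silhouette
    """

    def __init__(self, k_range=tuple(range(2, 11)), linkage_method: str = "ward"):
        self.k_range = k_range
        self.linkage_method = linkage_method

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        n = len(X)
        if n < 3:
            raise ValueError("need at least 3 samples to cluster")
        k_range = [k for k in self.k_range if 2 <= k <= n - 1]
        arr = X.to_numpy(dtype=float)
        if np.allclose(arr, arr[0]):
            warnings.warn(
                "all pairwise distances are zero; returning a single cluster",
                stacklevel=2,
            )
            self.k_, self.linkage_matrix_, self.silhouette_by_k_ = 1, None, {}
            self.labels_ = np.array(["G1"] * n, dtype=object)
            return self
        if not k_range:
            raise ValueError("k_range empty after clipping to [2, n_samples-1]")

        Z = linkage(arr, method=self.linkage_method)
        self.silhouette_by_k_ = {}
        best_k, best_sil, best_labels = None, -np.inf, None
        for k in k_range:
            flat = fcluster(Z, t=k, criterion="maxclust")
            if len(np.unique(flat)) < 2:
                continue
            sil = float(silhouette_score(arr, flat, metric="euclidean"))
            self.silhouette_by_k_[k] = sil
            if sil > best_sil + 1e-12:
                best_k, best_sil, best_labels = k, sil, flat
        if best_k is None:
            raise ValueError("clustering produced no valid partition")

        # rename clusters G1..Gk by decreasing size, ties by first member id
        ids = list(X.index)
        order = sorted(
            np.unique(best_labels),
            key=lambda c: (
                -int((best_labels == c).sum()),
                min(str(ids[i]) for i in np.nonzero(best_labels == c)[0]),
            ),
        )
        rename = {c: f"G{i + 1}" for i, c in enumerate(order)}
        self.labels_ = np.array([rename[c] for c in best_labels], dtype=object)
        self.k_ = len(np.unique(best_labels))
        self.linkage_matrix_ = Z
        return self


def cluster_patients(
    scores: pd.DataFrame,
    k_range=tuple(range(2, 11)),
    linkage_method: str = "ward",
) -> EndotypeAssignment:
    """Functional wrapper over :class:`EndotypeClusterer`."""
    est = EndotypeClusterer(k_range=k_range, linkage_method=linkage_method).fit(scores)
    return EndotypeAssignment(
        labels=pd.Series(est.labels_, index=scores.index, name="endotype"),
        k=est.k_,
        linkage_matrix=est.linkage_matrix_,
        silhouette_by_k=est.silhouette_by_k_,
    )


def group_gfc(scores: pd.DataFrame, assignment: EndotypeAssignment) -> pd.DataFrame:
    """Endotype x module group fold changes: within-group mean score capped
    to [-2, +2] (cap applied after the mean)."""
    missing = assignment.labels.index.difference(scores.index)
    if len(missing):
        raise ValueError(f"labeled samples missing from scores: {list(missing)[:5]}")
    out = {}
    for endo, members in assignment.labels.groupby(assignment.labels).groups.items():
        if len(members) == 0:
            raise ValueError(f"endotype {endo!r} is empty")
        out[endo] = scores.loc[members].mean(axis=0).clip(-GFC_CAP, GFC_CAP)
    return pd.DataFrame(out).T.sort_index()


def hypergeom_tail(overlap: int, universe: int, set_size: int, draws: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, draws))


def ora_annotate(
    modules: ModuleSet, collection: dict, universe: list
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in each module.

    BH adjustment runs across all (module, gene set) pairs.  Gene sets are
    intersected with the universe first; the universe must contain every
    module gene.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    module_genes = set().union(*modules.modules.values()) if modules.modules else set()
    if not module_genes <= universe_set:
        raise ValueError("universe must contain every module gene")
    rows = []
    for mod_name, genes in modules.modules.items():
        draws = set(genes)
        for set_name, members in collection.items():
            hits = set(members) & universe_set
            overlap = len(draws & hits)
            p = hypergeom_tail(overlap, len(universe_set), len(hits), len(draws))
            rows.append(
                {
                    "module": mod_name,
                    "gene_set": set_name,
                    "overlap": overlap,
                    "module_size": len(draws),
                    "set_size": len(hits),
                    "pvalue": min(p, 1.0),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def associate_clinical(
    assignment: EndotypeAssignment, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Test each clinical feature against the endotype labels.

    Numeric features: Kruskal-Wallis across endotypes.  Categorical
    features: Chi-squared on the endotype x category contingency table,
    without continuity correction.  Features constant across samples are
    flagged and given p = 1.
    """
    common = assignment.labels.index.intersection(clinical.index)
    labels = assignment.labels.loc[common]
    rows = []
    for feat in clinical.columns:
        values = clinical.loc[common, feat]
        mask = values.notna()
        v, g = values[mask], labels[mask]
        numeric = pd.api.types.is_numeric_dtype(v)
        if v.nunique() <= 1:
            rows.append(
                {
                    "feature": feat,
                    "test": "kruskal" if numeric else "chi2",
                    "statistic": np.nan,
                    "df": np.nan,
                    "pvalue": 1.0,
                    "flag": "constant",
                }
            )
            continue
        if numeric:
            groups = [v[g == e].to_numpy() for e in g.unique()]
            stat, p = stats.kruskal(*groups)
            df = len(groups) - 1
            test = "kruskal"
        else:
            table = pd.crosstab(g, v)
            stat, p, df, _ = stats.chi2_contingency(table, correction=False)
            test = "chi2"
        rows.append(
            {
                "feature": feat,
                "test": test,
                "statistic": float(stat),
                "df": float(df),
                "pvalue": float(p),
                "flag": "",
            }
        )
    return pd.DataFrame(rows)
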