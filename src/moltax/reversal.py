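"""Signature-reversal drug scoring.

Drug signatures are reduced to up/down gene sets (top 300 significant genes
by |log2FC|); each endotype's disease signature supplies a ranked gene list
(Wald statistics, descending); preranked GSEA with a permutation null gives
a normalized enrichment score (NES) per set; and the reversal score of a
drug against an endotype is dNES = NES(down set) - NES(up set).  A drug
whose down-regulated genes sit atop the disease ranking (and vice versa)
reverses the disease signature and earns a large positive dNES.  Drugs are
then k-means-clustered on their per-endotype dNES vectors with elbow-based
k selection, and per-endotype candidates are read from the best cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from ._utils import as_rng, derive_seed

__all__ = [
    "GeneSetPair",
    "RankedList",
    "EnrichmentResult",
    "signature_to_gene_sets",
    "make_ranked_list",
    "enrichment_score",
    "gsea_preranked",
    "delta_nes",
    "score_matrix",
    "DeltaNESKMeans",
    "kmeans_elbow",
    "top_drugs_for_group",
]


@dataclass
class GeneSetPair:
    signature_id: str
    up: list  # genes the drug up-regulates
    down: list  # genes the drug down-regulates

    @property
    def usable(self) -> bool:
        return bool(self.up) or bool(self.down)


@dataclass
class RankedList:
    """Genes ordered by descending score (ties broken by gene id)."""

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list contains duplicate genes")


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    pvalue: float
    n_perm: int
    seed: int
    n_hits: int


def make_ranked_list(scores: pd.Series) -> RankedList:
    """Build a RankedList from a gene -> score Series (e.g. Wald stats).

    NaN scores are dropped; ordering is score descending, then gene id
    ascending, which makes the ranking fully deterministic under ties.
    """
    s = scores.dropna()
    order = sorted(s.index, key=lambda g: (-s[g], str(g)))
    return RankedList(
        genes=np.asarray(order, dtype=object),
        scores=np.asarray([s[g] for g in order], dtype=float),
    )


def signature_to_gene_sets(
    sig: pd.DataFrame, alpha: float = 0.05, top_n: int = 300
) -> GeneSetPair:
    """Reduce one drug signature to its up/down gene sets.

    Rows with p < alpha are ordered by decreasing |log2fc| (ties by gene id),
    truncated to ``top_n``, and split by fold-change sign; zero-log2fc rows
    are discarded.  Expects columns gene, log2fc, pvalue and a single
    signature_id (used for labeling only).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    sig_ids = sig["signature_id"].unique() if "signature_id" in sig else ["signature"]
    if len(sig_ids) != 1:
        raise ValueError("signature_to_gene_sets expects exactly one signature")
    keep = sig.loc[(sig["pvalue"] < alpha) & (sig["log2fc"] != 0)]
    if keep.empty:
        warnings.warn(f"signature {sig_ids[0]!r}: no significant genes", stacklevel=2)
        return GeneSetPair(signature_id=str(sig_ids[0]), up=[], down=[])
    keep = keep.sort_values(
        ["log2fc", "gene"],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
    ).head(top_n)
    up = sorted(keep.loc[keep.log2fc > 0, "gene"])
    down = sorted(keep.loc[keep.log2fc < 0, "gene"])
    return GeneSetPair(signature_id=str(sig_ids[0]), up=up, down=down)


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_total: int, n_hits: int
) -> np.ndarray:
    """Vectorized enrichment scores for rows of sorted hit positions.

    positions, weights: (n_rows, k) with positions sorted ascending per row
    and weights already normalized to sum 1 per row.  The running sum gains
    w_i at each hit and loses 1/(N-k) at each miss; the ES is the deviation
    of largest magnitude (ties -> the positive one).
    """
    miss = 1.0 / (n_total - n_hits)
    idx = np.arange(n_hits)[None, :]
    after = np.cumsum(weights, axis=1) - (positions + 1 - (idx + 1)) * miss
    before = after - weights
    max_dev = after.max(axis=1)
    min_dev = np.minimum(before.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def enrichment_score(ranked: RankedList, gene_set) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score (weight exponent 1).

    Hits step up by |score| / sum of |score| over the set's in-list genes;
    misses step down by 1 / (N - n_hits); the ES is the extreme of the
    running sum.
    """
    n = len(ranked.genes)
    pos_map = {g: i for i, g in enumerate(ranked.genes)}
    positions = np.sort([pos_map[g] for g in gene_set if g in pos_map])
    k = positions.size
    if k == 0:
        raise ValueError("gene set has no genes in the ranked list")
    if k >= n:
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(ranked.scores[positions])
    total = w.sum()
    w = w / total if total > 0 else np.full(k, 1.0 / k)
    return float(_es_from_positions(positions[None, :], w[None, :], n, k)[0])


def _null_es(
    ranked: RankedList, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES values of n_perm random size-k gene sets from the ranked list."""
    n = len(ranked.genes)
    positions = np.empty((n_perm, k), dtype=np.int64)
    for i in range(n_perm):
        positions[i] = rng.choice(n, size=k, replace=False)
    positions.sort(axis=1)
    w = np.abs(ranked.scores)[positions]
    totals = w.sum(axis=1, keepdims=True)
    safe = totals.squeeze(1) > 0
    w = np.where(totals > 0, w / np.where(totals > 0, totals, 1.0), 1.0 / k)
    out = _es_from_positions(positions, w, n, k)
    if not safe.all():
        out[~safe] = 0.0
    return out


def gsea_preranked(
    ranked: RankedList, gene_set, n_perm: int = 1000, seed: int = 0
) -> EnrichmentResult:
    """Preranked GSEA of one gene set with a random-set permutation null.

    NES = ES / mean(|null ES| of the same sign as ES); the p-value is the
    one-sided permutation tail among same-sign null values, with +1
    smoothing so that p is never 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = as_rng(seed)
    in_list = set(ranked.genes)
    hits = [g for g in gene_set if g in in_list]
    es = enrichment_score(ranked, hits)  # validates the intersection
    null = _null_es(ranked, len(hits), n_perm, rng)
    same_sign = null >= 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes = 0.0
        pvalue = 1.0 / (n_perm + 1)
    else:
        denom = np.abs(null[same_sign]).mean()
        nes = es / denom if denom > 0 else 0.0
        pvalue = (1 + int((np.abs(null[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    return EnrichmentResult(
        es=es,
        nes=float(nes),
        pvalue=float(pvalue),
        n_perm=n_perm,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        n_hits=len(hits),
    )


def delta_nes(
    ranked: RankedList, pair: GeneSetPair, n_perm: int = 1000, seed: int = 0
) -> dict:
    """Reversal score of one drug against one endotype ranking.

    delta = NES(down set) - NES(up set).  Both sides share the same null
    seed, so identical up/down sets cancel exactly.  A side with no usable
    genes contributes 0 and is flagged.
    """
    if not pair.usable:
        raise ValueError(f"signature {pair.signature_id!r} has no usable gene sets")
    ranked_genes = set(ranked.genes)
    out = {"signature_id": pair.signature_id, "flags": []}
    for side, genes in (("up", pair.up), ("down", pair.down)):
        usable = [g for g in genes if g in ranked_genes]
        if genes and len(usable) < len(genes):
            out["flags"].append(f"{side}:dropped_{len(genes) - len(usable)}")
        if not usable or len(usable) >= len(ranked_genes):
            out[f"nes_{side}"] = 0.0
            out["flags"].append(f"{side}:missing")
        else:
            res = gsea_preranked(ranked, usable, n_perm=n_perm, seed=seed)
            out[f"nes_{side}"] = res.nes
    out["delta_nes"] = out["nes_down"] - out["nes_up"]
    out["flags"] = ";".join(out["flags"])
    return out


def score_matrix(
    rankings: dict[str, RankedList],
    library: list[GeneSetPair],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full signature x endotype dNES table.

    Each cell gets its own seed derived from (master seed, signature id,
    endotype), so results are independent of evaluation order.  Unusable
    cells are kept as NaN with a reason flag.
    """
    if not rankings:
        raise ValueError("need at least one endotype ranking")
    if len(library) < 2:
        raise ValueError("need at least two drug signatures")
    rows = []
    for pair in library:
        for endo, ranked in rankings.items():
            cell = {
                "signature_id": pair.signature_id,
                "endotype": endo,
                "nes_up": np.nan,
                "nes_down": np.nan,
                "delta_nes": np.nan,
                "flags": "",
            }
            if not pair.usable:
                cell["flags"] = "excluded:no_gene_sets"
            else:
                cell_seed = derive_seed(seed, pair.signature_id, endo)
                try:
                    res = delta_nes(ranked, pair, n_perm=n_perm, seed=cell_seed)
                except ValueError as exc:
                    cell["flags"] = f"excluded:{exc}"
                else:
                    cell.update(
                        nes_up=res["nes_up"],
                        nes_down=res["nes_down"],
                        delta_nes=res["delta_nes"],
                        flags=res["flags"],
                    )
            rows.append(cell)
    return pd.DataFrame(rows)


class DeltaNESKMeans(BaseEstimator, ClusterMixin):
    """K-means over per-endotype dNES vectors with elbow-selected k.

    For each k in ``k_range`` Lloyd's algorithm runs with ``n_init``
    restarts; the elbow is the interior k maximizing the relative curvature
    (WSS(k-1) - 2 WSS(k) + WSS(k+1)) / WSS(k) (ties -> smallest k), i.e.
    the k after which the WSS curve flattens relative to its own level.
    Degenerate input (all rows identical) reports k = 1 with a flag.

    Attributes: labels_, k_, wss_ (dict k -> WSS), degenerate_.
    """

    def __init__(self, k_range=tuple(range(1, 11)), n_init: int = 10, random_state: int = 0):
        self.k_range = k_range
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("X contains missing values; drop incomplete rows first")
        n = X.shape[0]
        k_range = sorted(k for k in self.k_range if 1 <= k <= n)
        if not k_range:
            raise ValueError("k_range empty after clipping to [1, n_rows]")
        self.degenerate_ = bool(np.allclose(X, X[0]))
        self.wss_ = {}
        models = {}
        for k in k_range:
            km = KMeans(
                n_clusters=k, n_init=self.n_init, random_state=self.random_state
            ).fit(X)
            self.wss_[k] = float(km.inertia_)
            models[k] = km
        if self.degenerate_ or (1 in self.wss_ and self.wss_[1] <= 1e-12):
            self.k_ = 1
            self.degenerate_ = True
        else:
            interior = [k for k in k_range if (k - 1) in self.wss_ and (k + 1) in self.wss_]
            if interior:
                total = max(self.wss_.values())
                curv = {
                    k: (self.wss_[k - 1] - 2 * self.wss_[k] + self.wss_[k + 1])
                    / max(self.wss_[k], 1e-12 * max(total, 1.0))
                    for k in interior
                }
                best = max(curv.values())
                self.k_ = min(k for k, v in curv.items() if v >= best - 1e-12)
            else:
                self.k_ = k_range[0]
        self.labels_ = (
            np.zeros(n, dtype=int) if self.k_ == 1 and 1 not in models
            else models[self.k_].labels_
        )
        return self


def kmeans_elbow(
    matrix: pd.DataFrame, k_range=tuple(range(1, 11)), seed: int = 0
) -> tuple[pd.Series, int, dict]:
    """Cluster drug signatures on their per-endotype dNES vectors.

    ``matrix`` is the long table from :func:`score_matrix`.  Signatures
    with any missing dNES cell are excluded (logged via warning).  Returns
    (labels: signature_id -> cluster id, chosen k, wss curve).
    """
    wide = matrix.pivot(index="signature_id", columns="endotype", values="delta_nes")
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"excluding {len(incomplete)} signature(s) with missing dNES: "
            f"{list(incomplete)[:5]}",
            stacklevel=2,
        )
        wide = wide.drop(index=incomplete)
    est = DeltaNESKMeans(k_range=k_range, random_state=seed).fit(wide.to_numpy())
    labels = pd.Series(est.labels_, index=wide.index, name="cluster")
    return labels, est.k_, est.wss_


def top_drugs_for_group(
    matrix: pd.DataFrame, clusters: pd.Series, endotype: str, n_top: int = 50
) -> pd.DataFrame:
    """Top candidate signatures for one endotype.

    Picks the drug cluster with the highest mean dNES for the endotype,
    then returns its ``n_top`` signatures by dNES descending (ties by
    signature id ascending).
    """
    sub = matrix.loc[matrix.endotype == endotype].copy()
    if sub.empty:
        raise ValueError(f"endotype {endotype!r} not present in the score matrix")
    sub["cluster"] = sub["signature_id"].map(clusters)
    sub = sub.dropna(subset=["cluster", "delta_nes"])
    best_cluster = sub.groupby("cluster")["delta_nes"].mean().idxmax()
    members = sub.loc[sub.cluster == best_cluster]
    members = members.sort_values(
        ["delta_nes", "signature_id"], ascending=[False, True]
    )
    return members.head(n_top).reset_index(drop=True)
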