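"""Co-expression network construction and module ("color") detection.

Pipeline: log2 size-factor normalization -> top-N variance filter -> Pearson
correlation graph at a scale-free-guided cutoff -> seeded Louvain community
detection -> named gene modules.  Edges use positive correlations only
(r >= cutoff), the usual co-expression-color convention: anti-correlated
genes fall into different modules on their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities, modularity
from sklearn.base import BaseEstimator

from .diffexp import size_factors

__all__ = [
    "NormalizedMatrix",
    "ModuleSet",
    "normalize",
    "select_variable_genes",
    "choose_cutoff",
    "build_graph",
    "detect_modules",
    "CoexpressionModules",
    "MODULE_COLORS",
]

#: fixed palette for module names, assigned in decreasing-size order
MODULE_COLORS = (
    "indianred",
    "darkgreen",
    "darkgrey",
    "pink",
    "darkorange",
    "orchid",
    "steelblue",
    "maroon",
    "gold",
    "plum",
    "lightblue",
    "sienna",
    "turquoise",
    "salmon",
    "khaki",
    "olive",
    "navy",
    "coral",
)

DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.5, 0.91, 0.05), 2))


@dataclass
class NormalizedMatrix:
    """log2(count / size_factor + 1) values with the size factors used."""

    values: pd.DataFrame  # gene x sample
    size_factors: pd.Series


@dataclass
class ModuleSet:
    """Disjoint named gene modules plus the genes left unassigned."""

    modules: dict  # name -> list of genes
    unassigned: list
    min_size: int

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def labels(self) -> pd.Series:
        """Gene -> module name, with unassigned genes labeled 'unassigned'."""
        pairs = [(g, name) for name, genes in self.modules.items() for g in genes]
        pairs += [(g, "unassigned") for g in self.unassigned]
        idx, lab = zip(*pairs) if pairs else ((), ())
        return pd.Series(lab, index=idx, name="module")


def normalize(counts: pd.DataFrame) -> NormalizedMatrix:
    """Median-of-ratios normalization followed by log2(x + 1).

    All-zero genes are retained (rows of zeros).  If the whole matrix is
    zero, size factors fall back to 1.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if mat.sum() == 0:
        sf = pd.Series(1.0, index=counts.columns, name="size_factor")
    else:
        sf = size_factors(counts)
    values = np.log2(mat / sf.to_numpy() + 1.0)
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=counts.index, columns=counts.columns),
        size_factors=sf,
    )


def select_variable_genes(norm: NormalizedMatrix, n_top: int = 10000) -> list:
    """The n_top genes with the largest variance across samples.

    Returned in decreasing-variance order (ties broken by gene id) and
    clamped to the number of available genes.
    """
    if n_top < 2:
        raise ValueError("n_top must be >= 2")
    var = norm.values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[: min(n_top, len(order))]


def _standardized(norm: NormalizedMatrix, genes: list) -> np.ndarray:
    x = norm.values.loc[genes].to_numpy(dtype=np.float32)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    sd[sd == 0] = np.inf  # constant genes correlate with nothing
    return x / sd[:, None]


def _scale_free_r2(degrees: np.ndarray) -> float:
    """R^2 of the log10(degree) vs log10(frequency) linear fit over
    non-isolated nodes; 0 when fewer than 3 distinct degrees exist."""
    deg = degrees[degrees > 0]
    if deg.size == 0:
        return 0.0
    uniq, freq = np.unique(deg, return_counts=True)
    if uniq.size < 3:
        return 0.0
    x, y = np.log10(uniq), np.log10(freq)
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def choose_cutoff(
    norm: NormalizedMatrix,
    candidates=DEFAULT_CUTOFFS,
    genes: list | None = None,
    min_retained: float = 0.5,
    r2_min: float = 0.8,
    block: int = 2000,
):
    """Pick a correlation cutoff from candidate r values.

    Returns ``(cutoff, diagnostics)`` where diagnostics is a per-candidate
    DataFrame (cutoff, scale_free_r2, n_nodes, n_edges, frac_retained).  The
    chosen cutoff is the smallest candidate whose graph has scale-free fit
    R^2 >= ``r2_min`` and retains at least ``min_retained`` of the input
    genes as non-isolated nodes; if none qualifies, the candidate with the
    highest R^2 (ties -> smallest cutoff).
    """
    candidates = [float(c) for c in candidates]
    if not candidates:
        raise ValueError("candidate list is empty")
    if any(not (0 < c < 1) for c in candidates):
        raise ValueError("candidates must lie in (0, 1)")
    if sorted(candidates) != candidates:
        raise ValueError("candidates must be sorted ascending")
    if genes is None:
        genes = list(norm.values.index)
    x = _standardized(norm, genes)
    n_genes, n_samples = x.shape
    degrees = np.zeros((len(candidates), n_genes), dtype=np.int64)
    for lo in range(0, n_genes, block):
        hi = min(lo + block, n_genes)
        corr = (x[lo:hi] @ x.T) / n_samples
        np.clip(corr, -1.0, 1.0, out=corr)
        for ci, c in enumerate(candidates):
            hits = corr >= c
            hits[np.arange(hi - lo), np.arange(lo, hi)] = False  # no self-edges
            degrees[ci, lo:hi] += hits.sum(axis=1)
    edge_counts = degrees.sum(axis=1) // 2

    rows = []
    for ci, c in enumerate(candidates):
        deg = degrees[ci]
        rows.append(
            {
                "cutoff": c,
                "scale_free_r2": _scale_free_r2(deg),
                "n_nodes": int((deg > 0).sum()),
                "n_edges": int(edge_counts[ci]),
                "frac_retained": float((deg > 0).mean()),
            }
        )
    diagnostics = pd.DataFrame(rows)
    ok = diagnostics[
        (diagnostics.scale_free_r2 >= r2_min)
        & (diagnostics.frac_retained >= min_retained)
    ]
    if len(ok):
        cutoff = float(ok.cutoff.iloc[0])
    else:
        cutoff = float(
            diagnostics.cutoff.iloc[int(diagnostics.scale_free_r2.to_numpy().argmax())]
        )
    return cutoff, diagnostics


def build_graph(
    norm: NormalizedMatrix, genes: list, cutoff: float, block: int = 2000
) -> nx.Graph:
    """Undirected graph over ``genes`` with edges where Pearson r >= cutoff."""
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    x = _standardized(norm, genes)
    n_genes, n_samples = x.shape
    g = nx.Graph()
    g.add_nodes_from(genes)
    genes_arr = np.asarray(genes, dtype=object)
    for lo in range(0, n_genes, block):
        hi = min(lo + block, n_genes)
        corr = (x[lo:hi] @ x.T) / n_samples
        np.clip(corr, -1.0, 1.0, out=corr)
        ii, jj = np.nonzero(corr >= cutoff)
        keep = (ii + lo) < jj  # upper triangle only, no self-edges
        g.add_weighted_edges_from(
            zip(genes_arr[ii[keep] + lo], genes_arr[jj[keep]], corr[ii[keep], jj[keep]])
        )
    return g


def detect_modules(
    graph: nx.Graph, min_size: int = 20, seed: int = 0, n_restarts: int = 5
) -> ModuleSet:
    """Louvain modules on the unweighted graph, named by a fixed palette.

    Runs seeded Louvain ``n_restarts`` times and keeps the partition with
    the highest modularity (ties -> first found).  Communities smaller than
    ``min_size`` go to unassigned; surviving modules are named from
    :data:`MODULE_COLORS` in decreasing-size order (ties by first gene id).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = sorted(graph.nodes())
    if graph.number_of_edges() == 0:
        warnings.warn("graph has no edges; all genes unassigned", stacklevel=2)
        return ModuleSet(modules={}, unassigned=nodes, min_size=min_size)

    active = graph.subgraph([n for n in nodes if graph.degree(n) > 0])
    rng = np.random.default_rng(seed)
    best, best_q = None, -np.inf
    for _ in range(max(1, n_restarts)):
        part = louvain_communities(active, weight=None, seed=int(rng.integers(2**31)))
        q = modularity(active, part, weight=None)
        if q > best_q + 1e-12:
            best, best_q = part, q

    communities = [sorted(c) for c in best if len(c) >= min_size]
    communities.sort(key=lambda c: (-len(c), c[0]))
    modules = {}
    for i, genes in enumerate(communities):
        name = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        modules[name] = genes
    assigned = set().union(*modules.values()) if modules else set()
    unassigned = sorted(set(nodes) - assigned)
    return ModuleSet(modules=modules, unassigned=unassigned, min_size=min_size)


class CoexpressionModules(BaseEstimator):
    """Detect co-expression modules from a raw count matrix.

    A scikit-learn-style estimator: ``fit`` takes a samples x genes count
    matrix (DataFrame; genes as columns) and exposes the discovered modules
    as fitted attributes.

    Parameters
    ----------
    n_top : int
        Number of most-variable genes fed to the network (10,000 mirrors the
        usual whole-blood co-expression setup).
    cutoff : "auto" or float
        Pearson-r edge threshold; "auto" runs the scale-free diagnostic over
        ``cutoff_candidates``.
    min_size : int
        Minimum community size to become a named module.
    random_state : int
        Seed for Louvain tie-breaking.

    Attributes
    ----------
    module_set_ : ModuleSet
    labels_ : pd.Series  gene -> module name ("unassigned" where dropped)
    cutoff_ : float
    diagnostics_ : pd.DataFrame or None
    genes_ : list  the variance-selected genes, decreasing variance
    """

    def __init__(
        self,
        n_top: int = 10000,
        cutoff="auto",
        cutoff_candidates=DEFAULT_CUTOFFS,
        min_size: int = 20,
        random_state: int = 0,
    ):
        self.n_top = n_top
        self.cutoff = cutoff
        self.cutoff_candidates = cutoff_candidates
        self.min_size = min_size
        self.random_state = random_state

    def fit(self, X, y=None):
        counts = pd.DataFrame(X)
        norm = normalize(counts.T)  # internal orientation: gene x sample
        self.size_factors_ = norm.size_factors
        self.genes_ = select_variable_genes(norm, self.n_top)
        if self.cutoff == "auto":
            self.cutoff_, self.diagnostics_ = choose_cutoff(
                norm, self.cutoff_candidates, genes=self.genes_
            )
        else:
            self.cutoff_, self.diagnostics_ = float(self.cutoff), None
        self.graph_ = build_graph(norm, self.genes_, self.cutoff_)
        self.module_set_ = detect_modules(
            self.graph_, min_size=self.min_size, seed=self.random_state
        )
        self.labels_ = self.module_set_.labels()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
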