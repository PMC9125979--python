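"""End-to-end study workflows: stratification and drug prediction.

These functions chain the library stages with one set of study parameters,
so tests, scripts and notebooks run the identical pipeline.  The default
correlation cutoff of 0.6 is derived from the synthetic generator's design
(within-module correlation ~ shared variance / total variance ~ 0.6-0.7,
background pairs ~ N(0, 1/sqrt(n_samples))); for empirical data use
``cutoff="auto"`` to run the scale-free diagnostic instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import coexpression as cx
from . import diffexp, reversal
from . import stratification as strat
from .synthetic import SyntheticCohort

__all__ = ["StratificationResult", "DrugPredictionResult", "stratify_cohort", "predict_drugs"]

SYNTHETIC_STUDY_CUTOFF = 0.6


@dataclass
class StratificationResult:
    norm: cx.NormalizedMatrix
    variable_genes: list
    cutoff: float
    module_set: cx.ModuleSet
    scores: pd.DataFrame  # sample x module
    assignment: strat.EndotypeAssignment
    gfc: pd.DataFrame


@dataclass
class DrugPredictionResult:
    signatures: dict  # endotype -> DE table
    rankings: dict  # endotype -> RankedList
    matrix: pd.DataFrame  # long dNES table
    clusters: pd.Series  # signature_id -> drug cluster
    k: int
    wss: dict


def stratify_cohort(
    counts: pd.DataFrame,
    patients: list,
    n_top: int = 10000,
    cutoff=SYNTHETIC_STUDY_CUTOFF,
    min_size: int = 20,
    k_range=tuple(range(2, 11)),
    seed: int = 0,
) -> StratificationResult:
    """Counts -> normalized matrix -> modules -> endotype assignment -> GFC.

    Controls participate in normalization, variance selection, the
    correlation graph and the gene-wise centering of module scores; only
    ``patients`` are clustered.
    """
    norm = cx.normalize(counts)
    genes = cx.select_variable_genes(norm, n_top)
    if cutoff == "auto":
        cutoff, _ = cx.choose_cutoff(norm, genes=genes)
    graph = cx.build_graph(norm, genes, float(cutoff))
    module_set = cx.detect_modules(graph, min_size=min_size, seed=seed)
    scores = strat.sample_module_scores(norm, module_set)
    assignment = strat.cluster_patients(scores.loc[patients], k_range=k_range)
    gfc = strat.group_gfc(scores.loc[patients], assignment)
    return StratificationResult(
        norm=norm,
        variable_genes=genes,
        cutoff=float(cutoff),
        module_set=module_set,
        scores=scores,
        assignment=assignment,
        gfc=gfc,
    )


def predict_drugs(
    counts: pd.DataFrame,
    controls: list,
    assignment: strat.EndotypeAssignment,
    library: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    top_n: int = 300,
    seed: int = 0,
) -> DrugPredictionResult:
    """Per-endotype DE vs controls, then dNES drug scoring and clustering.

    ``library`` is a long-format drug-signature table (signature_id,
    source, gene, log2fc, pvalue).
    """
    signatures = {}
    for endo in sorted(assignment.labels.unique()):
        members = assignment.labels.index[assignment.labels == endo].tolist()
        signatures[endo] = diffexp.de_test(counts, members, controls)
    rankings = {
        endo: reversal.make_ranked_list(de["wald"]) for endo, de in signatures.items()
    }
    pairs = [
        reversal.signature_to_gene_sets(grp, alpha=alpha, top_n=top_n)
        for _, grp in library.groupby("signature_id", sort=True)
    ]
    matrix = reversal.score_matrix(rankings, pairs, n_perm=n_perm, seed=seed)
    clusters, k, wss = reversal.kmeans_elbow(matrix, seed=seed)
    return DrugPredictionResult(
        signatures=signatures,
        rankings=rankings,
        matrix=matrix,
        clusters=clusters,
        k=k,
        wss=wss,
    )


def run_synthetic_study(cohort: SyntheticCohort, library, n_perm=1000, seed=0):
    """Stratify a synthetic cohort and, if a library is given, score drugs."""
    res = stratify_cohort(cohort.counts, cohort.patients, seed=seed)
    if library is None:
        return res, None
    drugs = predict_drugs(
        cohort.counts, cohort.controls, res.assignment, library, n_perm=n_perm, seed=seed
    )
    return res, drugs
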