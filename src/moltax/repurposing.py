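"""Drug repurposing: platform score filters, group-exclusive compound sets,
and a druggability re-ranking combining functional and structural scores.

The re-ranking is CoDReS-inspired: the functional component measures the
hypergeometric over-representation of a compound's genomic targets among
disease genes; the structural component is the fraction of passed
drug-likeness rules (Lipinski's rule of five plus Veber's rule).  Output
headers label the score "codres_inspired_combined" to flag the
approximation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stratification import hypergeom_tail

__all__ = [
    "CompoundDescriptors",
    "filter_ilincs",
    "filter_clue",
    "group_exclusive",
    "structural_score",
    "functional_score",
    "rank_candidates",
    "ILINCS_CUTOFF",
    "CLUE_CUTOFF",
]

#: concordance cutoff for iLINCS-style scores (range [-1, 1]), inclusive
ILINCS_CUTOFF = -0.5
#: connectivity cutoff for CLUE-style scores (range [-100, 100]), inclusive
CLUE_CUTOFF = -50.0

_PLATFORM_RANGE = {"ilincs": (-1.0, 1.0), "clue": (-100.0, 100.0)}


@dataclass
class CompoundDescriptors:
    """Molecular descriptors used by the structural (drug-likeness) score.

    Any field may be None (missing); the score denominator only counts
    evaluable rules.
    """

    molecular_weight: float | None = None  # Da
    logp: float | None = None
    hbd: int | None = None  # H-bond donors
    hba: int | None = None  # H-bond acceptors
    rotatable_bonds: int | None = None
    tpsa: float | None = None  # topological polar surface area, A^2


#: (descriptor attribute, rule) pairs: four Lipinski rules plus two Veber rules
DRUGLIKENESS_RULES = (
    ("molecular_weight", lambda v: v <= 500),
    ("logp", lambda v: v <= 5),
    ("hbd", lambda v: v <= 5),
    ("hba", lambda v: v <= 10),
    ("rotatable_bonds", lambda v: v <= 10),
    ("tpsa", lambda v: v <= 140),
)


def _filter(records: pd.DataFrame, platform: str, cutoff: float) -> pd.DataFrame:
    if records.empty:
        return records.copy()
    lo, hi = _PLATFORM_RANGE[platform]
    scores = records["score"].astype(float)
    valid = (scores >= lo) & (scores <= hi)
    if (~valid).any():
        bad = records.loc[~valid, "compound"].tolist()
        warnings.warn(
            f"{platform}: rejected {len(bad)} record(s) with out-of-range "
            f"scores (e.g. {bad[:3]})",
            stacklevel=3,
        )
    return records.loc[valid & (scores <= cutoff)].copy()


def filter_ilincs(records: pd.DataFrame, cutoff: float = ILINCS_CUTOFF) -> pd.DataFrame:
    """Keep iLINCS records with concordance score <= -0.5 (inclusive)."""
    return _filter(records, "ilincs", cutoff)


def filter_clue(records: pd.DataFrame, cutoff: float = CLUE_CUTOFF) -> pd.DataFrame:
    """Keep CLUE records with connectivity score <= -50 (inclusive)."""
    return _filter(records, "clue", cutoff)


def group_exclusive(per_endotype_sets: dict) -> tuple[dict, pd.DataFrame]:
    """Exclusive compound set per endotype plus the full Venn region table.

    exclusive(e) = set(e) minus the union of every other endotype's set.
    The Venn table has one row per non-empty membership pattern with its
    compound count; region counts sum to the size of the union.
    """
    endos = list(per_endotype_sets)
    if len(endos) < 2:
        raise ValueError("need at least 2 endotypes")
    sets = {e: set(per_endotype_sets[e]) for e in endos}
    exclusive = {
        e: sets[e] - set().union(*(sets[o] for o in endos if o != e)) for e in endos
    }
    rows = []
    for r in range(1, len(endos) + 1):
        for combo in itertools.combinations(endos, r):
            inside = set.intersection(*(sets[e] for e in combo))
            outside = set().union(*(sets[e] for e in endos if e not in combo), set())
            region = inside - outside
            if region:
                rows.append({"pattern": "&".join(combo), "count": len(region)})
    return exclusive, pd.DataFrame(rows, columns=["pattern", "count"])


def structural_score(d: CompoundDescriptors) -> tuple[float | None, int, bool]:
    """Fraction of passed drug-likeness rules among evaluable ones.

    Returns (score, n_evaluable, partial_flag); score is None when no
    descriptor is present.
    """
    passed = evaluable = 0
    for attr, rule in DRUGLIKENESS_RULES:
        v = getattr(d, attr)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        evaluable += 1
        passed += bool(rule(v))
    if evaluable == 0:
        return None, 0, True
    return passed / evaluable, evaluable, evaluable < len(DRUGLIKENESS_RULES)


def functional_score(
    compound_targets, disease_genes, universe, scale: float = 10.0
) -> tuple[float, bool]:
    """Disease-relevance of a compound's genomic targets, in [0, 1].

    min(1, -log10(p) / scale) where p is the hypergeometric upper-tail
    probability of the observed target/disease-gene overlap in the
    universe.  Empty target sets score 0 with a flag.
    """
    universe = set(universe)
    targets = set(compound_targets) & universe
    disease = set(disease_genes) & universe
    if not set(compound_targets) <= universe or not set(disease_genes) <= universe:
        raise ValueError("universe must contain both gene sets")
    if not targets:
        return 0.0, True
    overlap = len(targets & disease)
    p = hypergeom_tail(overlap, len(universe), len(disease), len(targets))
    return min(1.0, -np.log10(max(p, 1e-300)) / scale), False


def rank_candidates(
    records: pd.DataFrame,
    descriptors: dict,
    targets: dict,
    disease_genes,
    universe,
) -> pd.DataFrame:
    """Druggability re-ranking of threshold-filtered, group-exclusive records.

    Per compound: combined = mean of the available {structural, functional}
    components; compounds are ranked 1..n per endotype by combined
    descending, ties by compound id ascending.
    """
    rows = []
    for _, rec in records.iterrows():
        compound = rec["compound"]
        desc = descriptors.get(compound)
        s_score, _, s_partial = (
            structural_score(desc) if desc is not None else (None, 0, True)
        )
        f_score, f_flag = functional_score(
            targets.get(compound, set()), disease_genes, universe
        )
        parts = [v for v in (s_score, f_score) if v is not None]
        combined = float(np.mean(parts))
        flags = []
        if s_score is None:
            flags.append("no_descriptors")
        elif s_partial:
            flags.append("partial_descriptors")
        if f_flag:
            flags.append("no_targets")
        rows.append(
            {
                "compound": compound,
                "endotype": rec.get("endotype", ""),
                "structural": s_score,
                "functional": f_score,
                "codres_inspired_combined": combined,
                "flags": ";".join(flags),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["rank"] = []
        return out
    out = out.sort_values(
        ["endotype", "codres_inspired_combined", "compound"],
        ascending=[True, False, True],
    ).reset_index(drop=True)
    out["rank"] = out.groupby("endotype").cumcount() + 1
    return out
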