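"""Plain-text readers and writers: TSV tables, GMT gene sets, MatrixMarket
counts, and a Newick-style dendrogram serialization."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy.sparse import coo_matrix

from .coexpression import ModuleSet

__all__ = [
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "module_set_to_gmt",
    "read_drug_library",
    "linkage_to_newick",
]


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count table (TSV with gene-id index, or
    MatrixMarket .mtx with sibling <stem>.genes.txt / <stem>.samples.txt)."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = spio.mmread(path).tocsr().toarray()
        genes = Path(str(path.with_suffix("")) + ".genes.txt").read_text().split()
        samples = Path(str(path.with_suffix("")) + ".samples.txt").read_text().split()
        return pd.DataFrame(mat, index=genes, columns=samples)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "mtx":
        sparse = coo_matrix(counts.to_numpy())
        spio.mmwrite(path, sparse)
        base = str(path.with_suffix(""))
        Path(base + ".genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
        Path(base + ".samples.txt").write_text(
            "\n".join(map(str, counts.columns)) + "\n"
        )
    else:
        counts.to_csv(path, sep="\t")


def read_gmt(path) -> dict:
    """GMT file -> {set name: list of genes} (description field ignored)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict, path, description: str = "moltax") -> None:
    lines = [
        "\t".join([name, description] + list(map(str, genes)))
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def module_set_to_gmt(modules: ModuleSet, path) -> None:
    """Serialize a ModuleSet as GMT, with unassigned genes as a final set."""
    sets = dict(modules.modules)
    if modules.unassigned:
        sets["unassigned"] = modules.unassigned
    write_gmt(sets, path, description="coexpression-module")


def read_drug_library(path) -> pd.DataFrame:
    """Long-format drug-signature TSV with columns
    signature_id, source, gene, log2fc, pvalue."""
    df = pd.read_csv(path, sep="\t")
    required = {"signature_id", "source", "gene", "log2fc", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drug library missing columns: {sorted(missing)}")
    return df


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Scipy linkage matrix -> Newick string with merge-height branch lengths."""
    labels = list(labels)
    n = len(labels)

    def node(i: int, parent_height: float) -> str:
        if i < n:
            return f"{labels[i]}:{parent_height:.6g}"
        row = Z[i - n]
        h = row[2]
        left = node(int(row[0]), h)
        right = node(int(row[1]), h)
        return f"({left},{right}):{max(parent_height - h, 0.0):.6g}"

    root = 2 * n - 2
    return node(root, Z[-1][2]) + ";"
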