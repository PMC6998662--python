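"""Pathway over-representation analysis for differentially expressed RNAs.

Only mRNAs and the predicted targets of miRNAs/isomiRs carry functional
annotation; other circulating RNA classes have none and contribute nothing.
The selected gene set is tested pathway by pathway with the one-sided
hypergeometric tail (the classical over-representation test) against a
universe of all annotated genes, with BH adjustment across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import DEResult, adjust_bh

__all__ = [
    "PathwayResult",
    "read_target_table",
    "read_pathways",
    "select_genes",
    "pathway_test",
    "make_toy_annotations",
]


@dataclass
class PathwayResult:
    pathway_id: str
    pathway_name: str
    pathway_size: int
    overlap: int
    p: float
    padj: float


def read_target_table(path: str | Path) -> pd.DataFrame:
    """Read a miRNA->target prediction table (mirna_id, gene_id, score)."""
    df = pd.read_csv(path, sep="\t")
    required = {"mirna_id", "gene_id", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"target table needs columns {sorted(required)}")
    if ((df["score"] < 0) | (df["score"] > 100)).any():
        raise ValueError("target scores must lie in [0, 100]")
    return df


def read_pathways(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read pathway annotation TSV (pathway_id, pathway_name, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    required = {"pathway_id", "pathway_name", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"pathway table needs columns {sorted(required)}")
    pathways: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for pid, name, gene in df[["pathway_id", "pathway_name", "gene_id"]].itertuples(index=False):
        pathways.setdefault(str(pid), set()).add(str(gene))
        names[str(pid)] = str(name)
    return pathways, names


def select_genes(
    de_results: Sequence[DEResult],
    target_table: pd.DataFrame,
    score_cutoff: float = 60.0,
    isomir_parent: Mapping[str, str] | None = None,
    significant_only: bool = True,
    alpha: float = 0.05,
) -> set[str]:
    """Gene set for enrichment: DE mRNAs plus predicted miRNA/isomiR targets.

    mRNA ids are used directly as gene ids; targets enter only with a
    prediction score strictly greater than ``score_cutoff``.  isomiRs map to
    their parent miRNA's target list via ``isomir_parent``.  RNA classes
    without functional predictions (piRNA, tRF, ...) contribute nothing.
    An empty DE input yields an empty set.
    """
    if significant_only:
        de_results = [r for r in de_results if np.isfinite(r.padj) and r.padj < alpha]
    genes: set[str] = set()
    mirnas: set[str] = set()
    for r in de_results:
        if r.rna_class == "mRNA":
            genes.add(r.rna_id)
        elif r.rna_class == "miRNA":
            mirnas.add(r.rna_id)
        elif r.rna_class == "isomiR":
            parent = (isomir_parent or {}).get(r.rna_id)
            if parent is not None:
                mirnas.add(parent)
    if mirnas:
        hits = target_table[
            target_table["mirna_id"].isin(mirnas) & (target_table["score"] > score_cutoff)
        ]
        genes |= set(hits["gene_id"].astype(str))
    return genes


def pathway_test(
    gene_set: Iterable[str],
    pathways: Mapping[str, set[str]],
    universe: Iterable[str],
    pathway_names: Mapping[str, str] | None = None,
) -> list[PathwayResult]:
    """One-sided hypergeometric over-representation test per pathway.

    With universe size M, K annotated pathway genes, a selection of size n,
    and overlap x, ``p = P(X >= x)`` for X ~ Hypergeometric(M, K, n); BH
    adjustment is applied across pathways.  Genes outside the universe raise
    ``ValueError``.
    """
    universe = set(universe)
    selected = set(gene_set)
    outside = sorted(selected - universe)
    if outside:
        raise ValueError(f"genes outside universe: {outside[:10]}")
    M, n = len(universe), len(selected)
    rows = []
    for pid in sorted(pathways):
        in_universe = pathways[pid] & universe
        if not in_universe:
            raise ValueError(f"pathway {pid} shares no genes with the universe")
        K = len(in_universe)
        x = len(selected & in_universe)
        p = float(hypergeom.sf(x - 1, M, K, n))
        rows.append((pid, K, x, min(p, 1.0)))
    padj = adjust_bh([r[3] for r in rows])
    names = pathway_names or {}
    return [
        PathwayResult(
            pathway_id=pid,
            pathway_name=names.get(pid, pid),
            pathway_size=K,
            overlap=x,
            p=p,
            padj=float(q),
        )
        for (pid, K, x, p), q in zip(rows, padj)
    ]


def results_to_frame(results: Sequence[PathwayResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "pathway_name": r.pathway_name,
                "pathway_size": r.pathway_size,
                "overlap": r.overlap,
                "p": r.p,
                "padj": r.padj,
            }
            for r in results
        ]
    )


def make_toy_annotations(
    n_pathways: int = 30,
    n_genes: int = 500,
    n_mirnas: int = 40,
    targets_per_mirna: int = 25,
    seed: int = 0,
) -> tuple[dict[str, set[str]], dict[str, str], pd.DataFrame, dict[str, str]]:
    """Small synthetic pathway + target annotation for tests and demos.

    Returns ``(pathways, pathway_names, target_table, isomir_parent)``.
    Gene and miRNA ids follow the simulator's naming (``GENE####``,
    ``miR####``, ``iso####``) so a simulated cohort's mRNA/miRNA/isomiR
    features are annotated.  This is a synthetic stand-in annotation, not a
    real pathway database.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    pathways: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for k in range(n_pathways):
        pid = f"PW{k + 1:03d}"
        size = int(rng.integers(10, 60))
        members = rng.choice(n_genes, size=size, replace=False)
        pathways[pid] = {genes[i] for i in members}
        names[pid] = f"Toy pathway {k + 1}"
    rows = []
    for m in range(n_mirnas):
        mid = f"miR{m + 1:04d}"
        tgt = rng.choice(n_genes, size=targets_per_mirna, replace=False)
        scores = np.round(rng.uniform(0, 100, size=targets_per_mirna), 1)
        for g, sc in zip(tgt, scores):
            rows.append({"mirna_id": mid, "gene_id": genes[g], "score": float(sc)})
    targets = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "score"])
    isomir_parent = {f"iso{m + 1:04d}": f"miR{(m % n_mirnas) + 1:04d}" for m in range(2 * n_mirnas)}
    return pathways, names, targets, isomir_parent
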