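"""Benchmark harness: systems-genetics format reader, directed-edge metrics,
and a correlation baseline.

The reader targets the DREAM5 systems-genetics layout: one expression TSV
and one genotype TSV (each genes/variants x samples with a header row of
sample ids and the feature id in the first column) where every gene has
exactly one matching genotype variable, plus a two-column gold-standard
edge list (regulator, target). Edge matching in the metrics is DIRECTED:
predicting a -> b earns no credit for a gold edge b -> a.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ivselect import IVSet
from .core import marginal_cis_effect
from .pairs import InteractionCall

__all__ = [
    "GoldStandard",
    "read_dream5",
    "read_gold_standard",
    "f1_score",
    "calls_to_edges",
    "correlation_baseline",
    "dream5_iv_map",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GoldStandard:
    """Directed edge set (regulator -> target) of the true network."""

    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r} in gold standard")

    def __len__(self) -> int:
        return len(self.edges)


def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns; expected TSV with header row of sample ids")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate feature ids")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ValueError(f"{path}: non-numeric values; expected a numeric matrix")
    df.index = df.index.astype(str)
    return df


def read_gold_standard(path: str | Path) -> GoldStandard:
    """Two-column TSV (regulator, target), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["regulator", "target"], usecols=[0, 1], dtype=str)
    return GoldStandard(edges=frozenset(zip(df["regulator"], df["target"])))


def read_dream5(
    expression_path: str | Path,
    genotype_path: str | Path,
    gold_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GoldStandard | None]:
    """Load an expression/genotype pair where genotype rows mirror gene ids.

    Both matrices must share the identical sample columns. Genes without a
    genotype row are excluded (logged); matrices come back aligned row-for-row
    on gene id.
    """
    expr = _read_matrix(expression_path)
    geno = _read_matrix(genotype_path)
    if list(expr.columns) != list(geno.columns):
        raise ValueError(
            "expression and genotype sample columns differ "
            f"({expression_path} vs {genotype_path})"
        )
    common = [g for g in expr.index if g in set(geno.index)]
    missing = [g for g in expr.index if g not in set(geno.index)]
    if missing:
        logger.warning("excluding %d genes with no genotype row: %s", len(missing), missing[:5])
    if not common:
        raise ValueError("no genes shared between expression and genotype matrices")
    gold = read_gold_standard(gold_path) if gold_path is not None else None
    return expr.loc[common], geno.loc[common], gold


def dream5_iv_map(expression: pd.DataFrame, genotypes: pd.DataFrame) -> dict[str, IVSet]:
    """One-element instrument sets from the per-gene genotype variable."""
    iv_map: dict[str, IVSet] = {}
    for gene in expression.index:
        g = genotypes.loc[gene].to_numpy(dtype=float)
        snp_id = str(gene)  # instrument id == genotype row label
        if np.all(g == g[0]):
            logger.warning("gene %s: constant genotype, no instrument", gene)
            iv_map[str(gene)] = IVSet(gene_id=str(gene))
            continue
        eff = marginal_cis_effect(g, expression.loc[gene].to_numpy(dtype=float), snp_id=snp_id)
        iv_map[str(gene)] = IVSet(gene_id=str(gene), snp_ids=[snp_id], cis_effects=[eff])
    return iv_map


def calls_to_edges(calls: list[InteractionCall]) -> set[tuple[str, str]]:
    """Directed edge set implied by interaction calls (bidirectional -> both arcs)."""
    edges: set[tuple[str, str]] = set()
    for c in calls:
        if c.scenario in ("i_to_j", "bidirectional"):
            edges.add((c.pair.gene_i, c.pair.gene_j))
        if c.scenario in ("j_to_i", "bidirectional"):
            edges.add((c.pair.gene_j, c.pair.gene_i))
    return edges


def f1_score(
    predicted: set[tuple[str, str]],
    gold: GoldStandard,
) -> tuple[float, float, float]:
    """(precision, recall, F1) for directed edge sets.

    F1 is the harmonic mean 2PR/(P+R). Zero denominators (empty prediction
    or empty gold) yield 0 with a warning rather than an error.
    """
    tp = len(predicted & gold.edges)
    fp = len(predicted - gold.edges)
    fn = len(gold.edges - predicted)
    if tp + fp == 0:
        logger.warning("no predicted edges; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.warning("empty gold standard; recall set to 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def correlation_baseline(expression: pd.DataFrame, r_threshold: float) -> set[tuple[str, str]]:
    """Undirected correlation network as reciprocal directed arcs.

    Every gene pair with |Pearson r| strictly above the threshold appears in
    both directions — the naive comparator a causal method should beat on
    directed metrics.
    """
    X = expression.to_numpy(dtype=float)
    genes = [str(g) for g in expression.index]
    keep = X.std(axis=1) > 0
    X, genes = X[keep], [g for g, k in zip(genes, keep) if k]
    edges: set[tuple[str, str]] = set()
    if len(genes) < 2:
        return edges
    R = np.corrcoef(X)
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            if abs(R[a, b]) > r_threshold:
                edges.add((genes[a], genes[b]))
                edges.add((genes[b], genes[a]))
    return edges
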