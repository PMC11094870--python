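"""Real-data pipeline: configuration, standardization, matrix I/O, and the
stage-by-stage run that turns expression + genotypes into a called network.

Stage order: standardize -> per-gene instrument selection -> candidate
pairing -> pleiotropy filter -> bidirectional IVW testing -> Bonferroni ->
classification -> graph assembly -> Louvain clustering -> degree filter.
Every run writes an edge table, graph files, a cluster table and a JSON
manifest recording the configuration, seed and the funnel counts at each
filter stage, so any number in the outputs can be recomputed from the
manifest plus the inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ivselect import (
    DEFAULT_CIS_WINDOW_BP,
    DEFAULT_MAX_IVS,
    DEFAULT_P_ENTER,
    GeneAnnotation,
    IVSet,
    cis_window,
    select_independent_ivs,
    weak_iv_filter,
)
from .pairs import DEFAULT_ALPHA, calls_to_frame, infer_interactions
from .network import (
    DEFAULT_MIN_DEGREE,
    build_graph,
    clusters_to_frame,
    louvain_clusters,
    write_graph,
)

__all__ = ["RunConfig", "standardize", "read_matrix_tsv", "read_annotation", "run_pipeline"]

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_USAGE = 2
EXIT_DATA = 3


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialized verbatim into the manifest."""

    expression_path: str
    genotype_path: str
    annotation_path: str
    variant_path: str
    out_dir: str
    r_threshold: float = 0.75
    weak_iv_threshold: float | None = None
    cis_window_bp: int = DEFAULT_CIS_WINDOW_BP
    max_ivs: int = DEFAULT_MAX_IVS
    p_enter: float = DEFAULT_P_ENTER
    alpha: float = DEFAULT_ALPHA
    bonferroni: bool = True
    min_degree: int = DEFAULT_MIN_DEGREE
    seed: int = 0
    transpose: bool = False

    def validate(self) -> None:
        for name in ("expression_path", "genotype_path", "annotation_path", "variant_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if not (0 < self.r_threshold < 1):
            raise ValueError(f"r_threshold must be in (0, 1), got {self.r_threshold}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.cis_window_bp <= 0:
            raise ValueError("cis_window_bp must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to mean 0, variance 1 (population denominator n).

    Constant rows cannot be standardized and are dropped with a warning.
    Idempotent on already-standardized input.
    """
    X = matrix.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # ddof=0: exact unit variance per row
    keep = sd[:, 0] > 0
    if not keep.all():
        dropped = [str(g) for g, k in zip(matrix.index, keep) if not k]
        logger.warning("dropping %d constant rows: %s", len(dropped), dropped[:5])
    Z = (X[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(Z, index=matrix.index[keep], columns=matrix.columns)


def read_matrix_tsv(path: str | Path, transpose: bool = False) -> pd.DataFrame:
    """Features x samples TSV with feature ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    if df.empty:
        raise ValueError(f"{path}: empty matrix")
    df.index = df.index.astype(str)
    return df


def read_annotation(path: str | Path, zero_based: bool = False) -> list[GeneAnnotation]:
    """Gene annotation TSV: gene_id, chrom, tss (1-based; BED-like 0-based
    input converts with ``zero_based=True``)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    shift = 1 if zero_based else 0
    return [
        GeneAnnotation(gene_id=str(r.gene_id), chrom=str(r.chrom), tss=int(r.tss) + shift)
        for r in df.itertuples()
    ]


def read_variant_positions(path: str | Path, zero_based: bool = False) -> pd.DataFrame:
    """Variant position TSV: snp_id, chrom, pos (1-based unless flagged)."""
    df = pd.read_csv(path, sep="\t")
    if missing := {"snp_id", "chrom", "pos"} - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    if zero_based:
        df["pos"] = df["pos"].astype(int) + 1
    return df


def select_all_ivs(
    expression: pd.DataFrame,
    genotypes: pd.DataFrame,
    annotation: list[GeneAnnotation],
    variant_positions: pd.DataFrame,
    config: RunConfig,
) -> dict[str, IVSet]:
    """Cis window + stepwise selection (+ optional weak-IV filter) per gene."""
    iv_map: dict[str, IVSet] = {}
    annotated = {a.gene_id: a for a in annotation}
    for gene in expression.index:
        gene = str(gene)
        anno = annotated.get(gene)
        if anno is None:
            logger.warning("gene %s has no annotation; excluded", gene)
            iv_map[gene] = IVSet(gene_id=gene)
            continue
        snps = cis_window(anno, variant_positions, config.cis_window_bp)
        snps = [s for s in snps if s in genotypes.index]
        if not snps:
            iv_map[gene] = IVSet(gene_id=gene)
            continue
        ivs = select_independent_ivs(
            genotypes.loc[snps],
            expression.loc[gene].to_numpy(dtype=float),
            gene_id=gene,
            max_ivs=config.max_ivs,
            p_enter=config.p_enter,
        )
        if config.weak_iv_threshold is not None:
            ivs = weak_iv_filter(ivs, config.weak_iv_threshold)
        iv_map[gene] = ivs
    return iv_map


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full inference pipeline and write all outputs.

    Returns a results bundle: calls, graph, clusters, funnel counts and the
    manifest dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    expression = standardize(read_matrix_tsv(config.expression_path, config.transpose))
    genotypes = read_matrix_tsv(config.genotype_path, config.transpose)
    if list(expression.columns) != list(genotypes.columns):
        raise ValueError("expression and genotype sample columns differ")
    annotation = read_annotation(config.annotation_path)
    variants = read_variant_positions(config.variant_path)

    iv_map = select_all_ivs(expression, genotypes, annotation, variants, config)
    counts: dict = {}
    calls = infer_interactions(
        expression, genotypes, iv_map,
        r_threshold=config.r_threshold, alpha=config.alpha,
        bonferroni=config.bonferroni, counts=counts,
    )

    graph = build_graph(calls)
    clusters = louvain_clusters(graph, seed=config.seed)
    counts["nodes"] = graph.number_of_nodes()
    counts["arcs"] = graph.number_of_edges()
    counts["clusters"] = len(set(clusters.values()))

    edge_table = calls_to_frame(calls)
    edge_table.to_csv(out / "interactions.tsv", sep="\t", index=False, float_format="%.10g")
    write_graph(graph, out / "network.tsv", "tsv")
    write_graph(graph, out / "network.sif", "sif")
    cluster_table = clusters_to_frame(graph, clusters, config.min_degree) if clusters else \
        pd.DataFrame(columns=["gene_id", "cluster", "degree", "retained_flag"])
    cluster_table.to_csv(out / "clusters.tsv", sep="\t", index=False)

    manifest = {
        "tool": "mrggi",
        "version": __version__,
        "config": asdict(config),
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "calls": calls,
        "iv_map": iv_map,
        "graph": graph,
        "clusters": clusters,
        "edge_table": edge_table,
        "cluster_table": cluster_table,
        "counts": counts,
        "manifest": manifest,
    }
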