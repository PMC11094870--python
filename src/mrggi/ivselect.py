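"""Per-gene instrument selection.

A gene's instruments are independent cis-SNPs: variants within a window of
its transcription start site whose allele counts predict its expression and
which are not redundant with each other. Selection runs in four stages, each
its own function so real-data pipelines can recombine them:

1. :func:`cis_window` — restrict to variants near the TSS,
2. :func:`select_independent_ivs` — forward-stepwise conditional selection
   of non-redundant variants (the default fine-mapping stand-in; any
   callable with the same signature can replace it),
3. :func:`weak_iv_filter` — drop instruments with small absolute cis-effect,
4. :func:`top_k_ivs` — keep the strongest k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CisEffect, marginal_cis_effect

__all__ = [
    "GeneAnnotation",
    "IVSet",
    "cis_window",
    "select_independent_ivs",
    "weak_iv_filter",
    "top_k_ivs",
]

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW_BP = 1_000_000
DEFAULT_P_ENTER = 1e-3
DEFAULT_MAX_IVS = 10
DEFAULT_MAF_FLOOR = 0.01
DEFAULT_WEAK_IV_THRESHOLD = 0.2


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene location: identifier, chromosome and 1-based TSS position."""

    gene_id: str
    chrom: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"TSS must be >= 1 (1-based), got {self.tss} for {self.gene_id!r}")


@dataclass
class IVSet:
    """Selected instruments for one gene, ordered by decreasing |cis-effect|.

    ``cis_effects`` holds the MARGINAL univariate effects of the selected
    SNPs — the quantities the IVW estimator consumes — even though selection
    itself is conditional.
    """

    gene_id: str
    snp_ids: list[str] = field(default_factory=list)
    cis_effects: list[CisEffect] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.snp_ids) != len(self.cis_effects):
            raise ValueError("snp_ids and cis_effects must align")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError(f"duplicate snp ids in IVSet for {self.gene_id!r}")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def is_empty(self) -> bool:
        return len(self.snp_ids) == 0


def _sorted_by_effect(gene_id: str, effects: list[CisEffect]) -> IVSet:
    # decreasing |beta|, snp_id lexical order breaking ties — deterministic
    order = sorted(effects, key=lambda e: (-abs(e.beta), e.snp_id))
    return IVSet(gene_id=gene_id, snp_ids=[e.snp_id for e in order], cis_effects=order)


def cis_window(
    gene: GeneAnnotation,
    variant_positions: pd.DataFrame,
    window_bp: int = DEFAULT_CIS_WINDOW_BP,
) -> list[str]:
    """SNP ids on the gene's chromosome within ``window_bp`` of its TSS.

    The interval is closed on both ends: a variant exactly ``window_bp``
    away is included. ``variant_positions`` needs columns
    ``snp_id``, ``chrom``, ``pos`` (1-based).
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be > 0, got {window_bp}")
    required = {"snp_id", "chrom", "pos"}
    missing = required - set(variant_positions.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")

    on_chrom = variant_positions[variant_positions["chrom"].astype(str) == str(gene.chrom)]
    if on_chrom.empty:
        logger.warning("gene %s: chromosome %s absent from variant table", gene.gene_id, gene.chrom)
        return []
    dist = (on_chrom["pos"].astype(np.int64) - gene.tss).abs()
    return on_chrom.loc[dist <= window_bp, "snp_id"].astype(str).tolist()


def _maf(column: np.ndarray) -> float:
    freq = float(np.mean(column)) / 2.0
    return min(freq, 1.0 - freq)


def select_independent_ivs(
    genotypes: pd.DataFrame,
    expression: np.ndarray,
    gene_id: str = "gene",
    max_ivs: int = DEFAULT_MAX_IVS,
    p_enter: float = DEFAULT_P_ENTER,
    maf_floor: float = DEFAULT_MAF_FLOOR,
) -> IVSet:
    """Forward-stepwise conditional selection of independent cis instruments.

    At each step the candidate with the smallest conditional p-value —
    from the regression of expression on the already-selected variants plus
    the candidate — is added, until no candidate reaches ``p_enter`` or
    ``max_ivs`` is hit. Conditional p-values use the Frisch–Waugh–Lovell
    residual regression with a Student-t reference.

    ``genotypes`` is variants x samples (rows indexed by snp_id). Variants
    with minor allele frequency below ``maf_floor`` are dropped up front:
    near-monomorphic columns give unstable OLS standard errors.

    Returns an empty :class:`IVSet` when nothing is selectable.
    """
    y = np.asarray(expression, dtype=float)
    n = y.shape[0]
    if genotypes.shape[1] != n:
        raise ValueError(
            f"genotypes have {genotypes.shape[1]} samples but expression has {n}"
        )

    G = genotypes.to_numpy(dtype=float).T  # samples x variants
    snp_ids = [str(s) for s in genotypes.index]
    usable = [j for j in range(G.shape[1]) if _maf(G[:, j]) >= maf_floor]
    if not usable:
        logger.warning("gene %s: no polymorphic cis variants above MAF floor", gene_id)
        return IVSet(gene_id=gene_id)

    yc = y - y.mean()
    Gc = G[:, usable] - G[:, usable].mean(axis=0)
    ids = [snp_ids[j] for j in usable]

    selected: list[int] = []
    # residuals of y and of every candidate w.r.t. the selected set,
    # updated by Gram-Schmidt as variants enter the model
    ry = yc.copy()
    R = Gc.copy()
    active = list(range(len(ids)))

    while len(selected) < max_ivs and active:
        df = n - 2 - len(selected)  # intercept + selected + candidate
        if df < 1:
            break
        best_j, best_p, best_t = None, 1.0, 0.0
        rss_y = float(ry @ ry)
        for j in active:
            rj = R[:, j]
            sxx = float(rj @ rj)
            # collinear with selected set (e.g. perfect-LD duplicate):
            # no residual variance left, conditional p treated as 1
            if sxx <= 1e-10 * n:
                continue
            b = float(rj @ ry) / sxx
            rss = rss_y - b * b * sxx
            if rss <= 0:
                p, tstat = 0.0, math.inf
            else:
                tstat = b / math.sqrt(rss / df / sxx)
                p = 2.0 * stats.t.sf(abs(tstat), df)
            if p < best_p or (p == best_p and abs(tstat) > abs(best_t)):
                best_j, best_p, best_t = j, p, tstat
        if best_j is None or best_p >= p_enter:
            break
        selected.append(best_j)
        rj = R[:, best_j].copy()
        sxx = float(rj @ rj)
        ry = ry - (float(rj @ ry) / sxx) * rj
        R = R - np.outer(rj, rj @ R / sxx)
        active = [j for j in active if j != best_j]

    if not selected:
        logger.info("gene %s: no variant reached p_enter=%g", gene_id, p_enter)
        return IVSet(gene_id=gene_id)

    effects = [
        marginal_cis_effect(G[:, usable[j]], y, snp_id=ids[j]) for j in selected
    ]
    return _sorted_by_effect(gene_id, effects)


def weak_iv_filter(ivs: IVSet, min_abs_cis_effect: float = DEFAULT_WEAK_IV_THRESHOLD) -> IVSet:
    """Drop instruments whose absolute cis-effect is below the threshold.

    The boundary is kept: only strictly weaker instruments are removed.
    May return an empty set, in which case the gene drops out of pair
    testing. Idempotent.
    """
    kept = [e for e in ivs.cis_effects if abs(e.beta) >= min_abs_cis_effect]
    return _sorted_by_effect(ivs.gene_id, kept)


def top_k_ivs(ivs: IVSet, k: int) -> IVSet:
    """The k instruments with the largest |cis-effect| (ties by snp_id)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(ivs):
        logger.info("gene %s: requested %d IVs but only %d available", ivs.gene_id, k, len(ivs))
        k = len(ivs)
    ordered = _sorted_by_effect(ivs.gene_id, list(ivs.cis_effects))
    return IVSet(
        gene_id=ivs.gene_id,
        snp_ids=ordered.snp_ids[:k],
        cis_effects=ordered.cis_effects[:k],
    )
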