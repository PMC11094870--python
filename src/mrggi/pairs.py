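"""Bidirectional causal testing of correlated gene pairs.

The procedure for a pair of genes (g_i, g_j):

* pairs are candidates when their expression correlation clears a threshold,
* pairs whose instrument sets overlap are excluded (a shared cis-SNP that
  affects both genes violates the exclusion restriction — horizontal
  pleiotropy),
* each surviving pair is tested in both directions: g_i -> g_j pools the
  marginal effects of g_i's instruments on g_i (exposure side) and on g_j
  (outcome side); g_j -> g_i uses g_j's instruments,
* p-values are Bonferroni-adjusted over all directional tests performed,
* each pair is classified as independent, i->j, j->i, or bidirectional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CausalEstimate, ivw_estimate, marginal_cis_effect
from .ivselect import IVSet

__all__ = [
    "GenePair",
    "InteractionCall",
    "SCENARIOS",
    "candidate_pairs",
    "pleiotropy_filter",
    "test_pair",
    "bonferroni_adjust",
    "classify_interaction",
    "infer_interactions",
    "calls_to_frame",
]

logger = logging.getLogger(__name__)

SCENARIOS = ("independent", "i_to_j", "j_to_i", "bidirectional")

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GenePair:
    """Unordered candidate pair, stored with gene_i < gene_j lexically."""

    gene_i: str
    gene_j: str
    correlation: float

    def __post_init__(self) -> None:
        if self.gene_i == self.gene_j:
            raise ValueError(f"self-pair {self.gene_i!r}")
        if self.gene_i > self.gene_j:
            raise ValueError("pair must be stored with gene_i < gene_j lexically")
        if abs(self.correlation) > 1 + 1e-12:
            raise ValueError(f"|correlation| > 1: {self.correlation}")

    @classmethod
    def make(cls, a: str, b: str, correlation: float) -> "GenePair":
        i, j = sorted((a, b))
        return cls(gene_i=i, gene_j=j, correlation=float(correlation))


@dataclass
class InteractionCall:
    """Classified pair with both directional estimates and adjusted p-values."""

    pair: GenePair
    scenario: str
    est_ij: CausalEstimate | None
    est_ji: CausalEstimate | None
    p_ij_adj: float
    p_ji_adj: float


def candidate_pairs(expression: pd.DataFrame, r_threshold: float) -> list[GenePair]:
    """All unordered gene pairs with |Pearson r| strictly above the threshold.

    ``expression`` is genes x samples. Constant rows cannot be correlated and
    are excluded with a warning.
    """
    if not (0 < r_threshold < 1):
        raise ValueError(f"r_threshold must be in (0, 1), got {r_threshold}")
    X = expression.to_numpy(dtype=float)
    genes = [str(g) for g in expression.index]
    sd = X.std(axis=1)
    keep = sd > 0
    dropped = [g for g, k in zip(genes, keep) if not k]
    if dropped:
        logger.warning("excluding %d constant gene rows from pairing: %s", len(dropped), dropped[:5])
    X = X[keep]
    genes = [g for g, k in zip(genes, keep) if k]
    if len(genes) < 2:
        return []
    R = np.corrcoef(X)
    pairs: list[GenePair] = []
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            if abs(R[a, b]) > r_threshold:
                pairs.append(GenePair.make(genes[a], genes[b], R[a, b]))
    return pairs


def pleiotropy_filter(pairs: Sequence[GenePair], iv_map: Mapping[str, IVSet]) -> list[GenePair]:
    """Drop pairs whose instrument sets share at least one SNP id."""
    kept: list[GenePair] = []
    for pair in pairs:
        ivs_i = iv_map[pair.gene_i]
        ivs_j = iv_map[pair.gene_j]
        shared = set(ivs_i.snp_ids) & set(ivs_j.snp_ids)
        if shared:
            logger.info("pair (%s, %s) removed: shared instruments %s", pair.gene_i, pair.gene_j, sorted(shared))
        else:
            kept.append(pair)
    return kept


def _directional_estimate(
    exposure: str,
    outcome: str,
    ivs: IVSet,
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
) -> CausalEstimate | None:
    if ivs.is_empty:
        return None
    y_exp = expression.loc[exposure].to_numpy(dtype=float)
    y_out = expression.loc[outcome].to_numpy(dtype=float)
    exp_effects = []
    out_effects = []
    for snp in ivs.snp_ids:
        g = genotypes.loc[snp].to_numpy(dtype=float)
        exp_effects.append(marginal_cis_effect(g, y_exp, snp_id=snp))
        out_effects.append(marginal_cis_effect(g, y_out, snp_id=snp))
    return ivw_estimate(exp_effects, out_effects, exposure_gene=exposure, outcome_gene=outcome)


def test_pair(
    pair: GenePair,
    iv_map: Mapping[str, IVSet],
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
) -> tuple[CausalEstimate | None, CausalEstimate | None]:
    """IVW estimates for both directions of one pair.

    The i->j direction instruments with gene_i's IV set; j->i with gene_j's.
    A direction whose exposure gene has no instruments is returned as None
    and later treated as non-significant.
    """
    est_ij = _directional_estimate(pair.gene_i, pair.gene_j, iv_map[pair.gene_i], genotypes, expression)
    est_ji = _directional_estimate(pair.gene_j, pair.gene_i, iv_map[pair.gene_j], genotypes, expression)
    return est_ij, est_ji


def bonferroni_adjust(p_values: Iterable[float], m: int) -> list[float]:
    """Bonferroni correction: min(1, p * m) elementwise.

    ``m`` is the total number of directional tests performed in the run.
    """
    ps = list(p_values)
    if m < len(ps):
        raise ValueError(f"m={m} smaller than number of p-values ({len(ps)})")
    out = []
    for p in ps:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value out of [0, 1]: {p}")
        out.append(min(1.0, p * m))
    return out


def classify_interaction(
    p_ij_adj: float | None,
    p_ji_adj: float | None,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Four-scenario truth table on adjusted p-values.

    Significance is strict (p_adj < alpha); an absent direction (None) is
    non-significant by construction.
    """
    sig_ij = p_ij_adj is not None and p_ij_adj < alpha
    sig_ji = p_ji_adj is not None and p_ji_adj < alpha
    if sig_ij and sig_ji:
        return "bidirectional"
    if sig_ij:
        return "i_to_j"
    if sig_ji:
        return "j_to_i"
    return "independent"


def infer_interactions(
    expression: pd.DataFrame,
    genotypes: pd.DataFrame,
    iv_map: Mapping[str, IVSet],
    r_threshold: float,
    alpha: float = DEFAULT_ALPHA,
    bonferroni: bool = True,
    counts: dict | None = None,
) -> list[InteractionCall]:
    """Candidate selection -> pleiotropy filter -> bidirectional IVW -> calls.

    Genes without instruments never enter candidate pairing. ``counts``, if
    given, is filled with the funnel sizes at each stage.
    """
    testable = expression.loc[[g for g in expression.index if not iv_map.get(str(g), IVSet(str(g))).is_empty]]
    pairs = candidate_pairs(testable, r_threshold)
    surviving = pleiotropy_filter(pairs, iv_map)

    results = [test_pair(p, iv_map, genotypes, expression) for p in surviving]
    n_tests = sum((e is not None) for pair_ests in results for e in pair_ests)
    if counts is not None:
        counts.update(
            genes_total=expression.shape[0],
            genes_with_ivs=testable.shape[0],
            candidate_pairs=len(pairs),
            pairs_after_pleiotropy=len(surviving),
            directional_tests=n_tests,
        )

    m = n_tests if bonferroni else 1
    calls: list[InteractionCall] = []
    for pair, (est_ij, est_ji) in zip(surviving, results):
        p_ij = bonferroni_adjust([est_ij.p], m)[0] if est_ij is not None else None
        p_ji = bonferroni_adjust([est_ji.p], m)[0] if est_ji is not None else None
        scenario = classify_interaction(p_ij, p_ji, alpha)
        calls.append(
            InteractionCall(
                pair=pair,
                scenario=scenario,
                est_ij=est_ij,
                est_ji=est_ji,
                p_ij_adj=float("nan") if p_ij is None else p_ij,
                p_ji_adj=float("nan") if p_ji is None else p_ji,
            )
        )
    if counts is not None:
        counts["non_independent_calls"] = sum(c.scenario != "independent" for c in calls)
    return calls


def calls_to_frame(calls: Sequence[InteractionCall]) -> pd.DataFrame:
    """Flatten calls into the edge-table layout written by the pipeline."""
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_i": c.pair.gene_i,
                "gene_j": c.pair.gene_j,
                "scenario": c.scenario,
                "beta_ij": c.est_ij.beta_hat if c.est_ij else np.nan,
                "se_ij": c.est_ij.se if c.est_ij else np.nan,
                "p_ij": c.est_ij.p if c.est_ij else np.nan,
                "p_ij_adj": c.p_ij_adj,
                "beta_ji": c.est_ji.beta_hat if c.est_ji else np.nan,
                "se_ji": c.est_ji.se if c.est_ji else np.nan,
                "p_ji": c.est_ji.p if c.est_ji else np.nan,
                "p_ji_adj": c.p_ji_adj,
                "n_ivs_i": c.est_ij.n_ivs if c.est_ij else 0,
                "n_ivs_j": c.est_ji.n_ivs if c.est_ji else 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_i", "gene_j", "scenario",
            "beta_ij", "se_ij", "p_ij", "p_ij_adj",
            "beta_ji", "se_ji", "p_ji", "p_ji_adj",
            "n_ivs_i", "n_ivs_j",
        ],
    )
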