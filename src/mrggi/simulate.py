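"""Synthetic-data generation and the simulation-study runners.

The generative model for a two-gene draw:

    g1 = S1 @ b1 + u1 + e1
    g2 = S2 @ b2 + beta_g1g2 * g1 + u2 + e2

where S1, S2 are allele-count matrices with entries ~ Binomial(2, MAF)
(additive coding), b1, b2 are the per-SNP cis effects, (u1, u2) are optional
confounders drawn per sample from a bivariate normal with unit variances and
correlation rho, and e1, e2 ~ N(0, 1) i.i.d. residuals.

The study runners sweep this model over the standard designs — varying the
number of instruments, instrument strength, confounder correlation and the
causal effect — and tabulate false-positive rates and power of the
directional IVW Wald test. A single seed streams every replicate through a
counter-based substream scheme (cell index, replicate index), so any single
replicate can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "EFFECTS_1IV",
    "EFFECTS_3IV",
    "EFFECTS_5IV",
    "WEAK_IV_SETS",
    "RHO_GRID",
    "BETA_GRID",
    "simulate_genotypes",
    "simulate_confounders",
    "simulate_pair",
    "directional_ivw_z",
    "run_fpr_study",
    "run_power_study",
    "simulate_network",
]

# effect-size sets used throughout the simulation studies
EFFECTS_1IV = (0.6,)
EFFECTS_3IV = (0.55, 0.4, 0.25)
EFFECTS_5IV = (0.55, 0.4, 0.35, 0.3, 0.25)
WEAK_IV_SETS = {1: (0.4, 0.3, 0.1), 2: (0.4, 0.1, 0.1), 3: (0.1, 0.1, 0.1)}
RHO_GRID = (-0.9, -0.5, -0.2, 0.0, 0.2, 0.5, 0.9)
BETA_GRID = (-0.7, -0.5, -0.3, -0.15, -0.05, -0.025, 0.0, 0.025, 0.05, 0.15, 0.3, 0.5, 0.7)

DEFAULT_MAF = 0.3
DEFAULT_N_SAMPLES = 1000

# substream offsets so every study design draws from a disjoint key space
_STREAM = {"iv_count": 0, "weak_iv": 100, "confounded": 200, "power_rho": 1000, "power_iv": 3000}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one two-gene generative-model draw."""

    n_samples: int = DEFAULT_N_SAMPLES
    maf: float = DEFAULT_MAF
    cis_effects_g1: tuple[float, ...] = EFFECTS_3IV
    cis_effects_g2: tuple[float, ...] = EFFECTS_3IV
    beta_g1g2: float = 0.0
    rho: float = 0.0
    include_confounders: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf < 0.5):
            raise ValueError(f"maf must be in (0, 0.5), got {self.maf}")
        if not (-1 < self.rho < 1):
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if self.n_samples < 10:
            raise ValueError(f"n_samples must be >= 10, got {self.n_samples}")


@dataclass
class SimulatedDataset:
    """One draw from the generative model, with its true parameters kept."""

    genotypes_g1: np.ndarray  # samples x SNPs, entries in {0, 1, 2}
    genotypes_g2: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    truth: SimulationConfig


def _rng(seed: int, spawn_key: tuple[int, ...] = ()) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn_key))


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf: float = DEFAULT_MAF,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Additively coded genotypes, entries i.i.d. Binomial(2, maf)."""
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    return rng.binomial(2, maf, size=(n_samples, n_snps))


def simulate_confounders(
    n_samples: int,
    rho: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample confounder pair from MVN(0, [[1, rho], [rho, 1]]).

    Drawn as u1 = a, u2 = rho*a + sqrt(1 - rho^2)*b with a, b independent
    standard normals — the exact Cholesky factorization of the target
    covariance.
    """
    if not (-1 < rho < 1):
        raise ValueError(f"|rho| must be < 1, got {rho}")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    ab = rng.standard_normal((n_samples, 2))
    u1 = ab[:, 0]
    u2 = rho * ab[:, 0] + math.sqrt(1.0 - rho * rho) * ab[:, 1]
    return u1, u2


def simulate_pair(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Draw one two-gene dataset from the generative model."""
    rng = rng if rng is not None else _rng(config.seed)
    n = config.n_samples
    b1 = np.asarray(config.cis_effects_g1, dtype=float)
    b2 = np.asarray(config.cis_effects_g2, dtype=float)
    S1 = simulate_genotypes(n, b1.size, config.maf, rng)
    S2 = simulate_genotypes(n, b2.size, config.maf, rng)
    if config.include_confounders:
        u1, u2 = simulate_confounders(n, config.rho, rng)
    else:
        u1 = u2 = 0.0
    e = rng.standard_normal((n, 2))
    g1 = S1 @ b1 + u1 + e[:, 0]
    g2 = S2 @ b2 + config.beta_g1g2 * g1 + u2 + e[:, 1]
    return SimulatedDataset(genotypes_g1=S1, genotypes_g2=S2, g1=g1, g2=g2, truth=config)


def directional_ivw_z(
    S: np.ndarray,
    g_exposure: np.ndarray,
    g_outcome: np.ndarray,
) -> tuple[float, float, float]:
    """IVW (beta_hat, se, z) for one direction, closed form.

    ``S`` holds the exposure gene's instruments (samples x SNPs). Marginal
    univariate OLS slopes of each instrument on exposure and outcome are
    pooled with inverse-variance weights from the outcome-side regressions.
    Identical to chaining ``marginal_cis_effect`` and ``ivw_estimate``; this
    array form is what the replicate loops call.
    """
    n = S.shape[0]
    Sc = S - S.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Sc, Sc)
    if np.any(sxx == 0):
        raise ValueError("constant instrument column")
    xc = g_exposure - g_exposure.mean()
    yc = g_outcome - g_outcome.mean()
    bx = Sc.T @ xc / sxx
    by = Sc.T @ yc / sxx
    rss = np.maximum(float(yc @ yc) - by * by * sxx, 0.0)
    se2 = rss / (n - 2) / sxx
    w = 1.0 / se2
    denom = float(bx * bx @ w)
    beta_hat = float(bx * by @ w) / denom
    se = math.sqrt(1.0 / denom)
    return beta_hat, se, beta_hat / se


def _p_from_z(z: float) -> float:
    # two-sided standard-normal tail; erfc avoids a scipy call in the hot loop
    return math.erfc(abs(z) / math.sqrt(2.0))


def _replicate_p(config: SimulationConfig, seed: int, cell: int, rep: int, top_k: int | None = None
                 ) -> tuple[float, float]:
    """(beta_hat, unadjusted p) of the g1 -> g2 test for one replicate."""
    data = simulate_pair(config, rng=_rng(seed, spawn_key=(cell, rep)))
    S = data.genotypes_g1
    if top_k is not None:
        # simulated effects are listed in decreasing order, so the top-k
        # instruments by |effect| are the leading columns
        S = S[:, :top_k]
    beta_hat, _, z = directional_ivw_z(S, data.g1, data.g2)
    return beta_hat, _p_from_z(z)


def run_fpr_study(
    design: str,
    n_reps: int = 10_000,
    cutoffs: tuple[float, ...] = (0.01, 0.05, 0.1),
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> pd.DataFrame:
    """False-positive rate of the directional test under a null design.

    Designs (all with beta_g1g2 = 0, MAF 0.3, both genes sharing the same
    cis-effect set):

    - ``"iv_count"``  — 1, 3 or 5 instruments, no confounders.
    - ``"weak_iv"``   — 3 instruments with 1, 2 or 3 weak (0.1) effects,
      no confounders.
    - ``"confounded"``— 3 instruments plus correlated confounders over the
      rho grid [-0.9 ... 0.9].

    Returns a tidy frame: design, cell, cutoff, n_reps, fpr — one row per
    (cell, cutoff), where the FPR is the fraction of replicates whose
    g1 -> g2 unadjusted Wald p falls below the cutoff.
    """
    if design == "iv_count":
        cells = [(k, SimulationConfig(n_samples=n_samples,
                                      cis_effects_g1=eff, cis_effects_g2=eff))
                 for k, eff in ((1, EFFECTS_1IV), (3, EFFECTS_3IV), (5, EFFECTS_5IV))]
    elif design == "weak_iv":
        cells = [(k, SimulationConfig(n_samples=n_samples,
                                      cis_effects_g1=eff, cis_effects_g2=eff))
                 for k, eff in sorted(WEAK_IV_SETS.items())]
    elif design == "confounded":
        cells = [(rho, SimulationConfig(n_samples=n_samples, rho=rho, include_confounders=True))
                 for rho in RHO_GRID]
    else:
        raise ValueError(f"unknown design {design!r}")

    rows = []
    base = _STREAM[design]
    for idx, (cell, config) in enumerate(cells):
        ps = np.fromiter(
            (_replicate_p(config, seed, base + idx, rep)[1] for rep in range(n_reps)),
            dtype=float,
            count=n_reps,
        )
        for cutoff in cutoffs:
            rows.append(
                {"design": design, "cell": cell, "cutoff": cutoff,
                 "n_reps": n_reps, "fpr": float(np.mean(ps < cutoff))}
            )
    return pd.DataFrame(rows)


def run_power_study(
    beta_grid: tuple[float, ...] = BETA_GRID,
    rho_grid: tuple[float, ...] = (0.0,),
    iv_counts: tuple[int, ...] | None = None,
    n_reps: int = 1000,
    n_samples: int = DEFAULT_N_SAMPLES,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical power of the directional test over a causal-effect grid.

    Two designs share this runner:

    - confounder sweep (``iv_counts=None``): 3 instruments per gene,
      confounders included, one power curve per rho in ``rho_grid``;
    - instrument-count sweep (``iv_counts`` given): 5 simulated instruments,
      no confounders, the top-k by |effect| used in the test for each k.

    Power is the fraction of replicates whose g1 -> g2 unadjusted Wald p is
    below ``alpha``. Tidy output: beta, rho, iv_count, n_reps, power.
    """
    # Common random numbers: every cell of one runner call replays the same
    # per-replicate substream, so differences along the beta grid (and across
    # iv_count or rho) reflect the parameter change rather than independent
    # sampling noise — the standard variance-reduction design for comparing
    # points on a power curve.
    rows = []
    if iv_counts is None:
        stream = _STREAM["power_rho"]
        for rho in rho_grid:
            for beta in beta_grid:
                config = SimulationConfig(
                    n_samples=n_samples, beta_g1g2=beta, rho=rho, include_confounders=True
                )
                hits = sum(
                    _replicate_p(config, seed, stream, rep)[1] < alpha
                    for rep in range(n_reps)
                )
                rows.append({"beta": beta, "rho": rho, "iv_count": 3,
                             "n_reps": n_reps, "power": hits / n_reps})
    else:
        stream = _STREAM["power_iv"]
        for k in iv_counts:
            for beta in beta_grid:
                config = SimulationConfig(
                    n_samples=n_samples, beta_g1g2=beta,
                    cis_effects_g1=EFFECTS_5IV, cis_effects_g2=EFFECTS_5IV,
                )
                hits = sum(
                    _replicate_p(config, seed, stream, rep, top_k=k)[1] < alpha
                    for rep in range(n_reps)
                )
                rows.append({"beta": beta, "rho": 0.0, "iv_count": k,
                             "n_reps": n_reps, "power": hits / n_reps})
    return pd.DataFrame(rows)


def simulate_network(
    edges: list[tuple[int, int, float]],
    n_genes: int,
    n_samples: int = DEFAULT_N_SAMPLES,
    cis_effects: tuple[float, ...] = EFFECTS_3IV,
    maf: float = DEFAULT_MAF,
    seed: int = 0,
    gene_spacing_bp: int = 10_000_000,
    snp_offset_bp: int = 1000,
) -> dict:
    """Many-gene extension of the pair model, for end-to-end evaluation.

    Genes are laid out on one chromosome ``gene_spacing_bp`` apart (wide
    enough that cis windows never overlap); each gene gets its own private
    cis-SNPs placed ``snp_offset_bp`` apart starting just downstream of its
    TSS. Expression is generated in topological order:

        g_v = S_v @ b + sum_{u -> v} beta_uv * g_u + e_v,  e_v ~ N(0, 1)

    ``edges`` lists (source_index, target_index, effect) with indices in
    0..n_genes-1; the induced graph must be acyclic.

    Returns a dict with ``expression`` (genes x samples), ``genotypes``
    (SNPs x samples), ``annotation``, ``variant_positions`` (DataFrames) and
    ``truth_edges`` (directed gene-id pairs).
    """
    import networkx as nx

    dag = nx.DiGraph()
    dag.add_nodes_from(range(n_genes))
    dag.add_edges_from([(u, v) for u, v, _ in edges])
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("edge list must induce a DAG")
    effect = {(u, v): w for u, v, w in edges}

    rng = _rng(seed)
    b = np.asarray(cis_effects, dtype=float)
    gene_ids = [f"g{i + 1:02d}" for i in range(n_genes)]
    expr = np.zeros((n_genes, n_samples))
    geno_rows, snp_ids, var_rows, anno_rows = [], [], [], []

    genotype_of = {}
    for i in range(n_genes):
        S = simulate_genotypes(n_samples, b.size, maf, rng)
        genotype_of[i] = S
        tss = (i + 1) * gene_spacing_bp
        anno_rows.append({"gene_id": gene_ids[i], "chrom": "1", "tss": tss})
        for k in range(b.size):
            sid = f"{gene_ids[i]}_s{k + 1}"
            snp_ids.append(sid)
            geno_rows.append(S[:, k])
            var_rows.append({"snp_id": sid, "chrom": "1", "pos": tss + (k + 1) * snp_offset_bp})

    for v in nx.topological_sort(dag):
        g = genotype_of[v] @ b + rng.standard_normal(n_samples)
        for u in dag.predecessors(v):
            g = g + effect[(u, v)] * expr[u]
        expr[v] = g

    sample_ids = [f"sample{j + 1}" for j in range(n_samples)]
    return {
        "expression": pd.DataFrame(expr, index=gene_ids, columns=sample_ids),
        "genotypes": pd.DataFrame(np.array(geno_rows), index=snp_ids, columns=sample_ids),
        "annotation": pd.DataFrame(anno_rows),
        "variant_positions": pd.DataFrame(var_rows),
        "truth_edges": {(gene_ids[u], gene_ids[v]) for u, v, _ in edges},
    }
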