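"""Closed-form Mendelian-randomization mathematics.

This module holds the statistical core used everywhere else: the marginal
(univariate) regression of a gene's expression on a single SNP, the Wald
ratio for a single instrument, the inverse-variance weighted (IVW) pooling
of several instruments, and the Wald hypothesis test on the pooled causal
effect.

All expression values are assumed to be on a common (typically standardized)
scale; the functions here are pure computations with no I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CisEffect",
    "CausalEstimate",
    "DegenerateInstrumentError",
    "marginal_cis_effect",
    "wald_ratio",
    "ivw_estimate",
    "wald_test",
]


class DegenerateInstrumentError(ValueError):
    """Raised when an instrument carries no usable signal (constant genotype,
    zero exposure effect, ...)."""


@dataclass(frozen=True)
class CisEffect:
    """Effect of one SNP on one gene from a univariate OLS fit with intercept.

    Attributes
    ----------
    snp_id : str
        Variant identifier.
    beta : float
        OLS slope — expression change per additional allele. On standardized
        expression this is the "cis-effect" when the SNP lies near the gene.
    se : float
        Standard error of ``beta``; strictly positive for any noisy fit,
        exactly 0 only in the noiseless degenerate case.
    n : int
        Number of samples in the regression.
    """

    snp_id: str
    beta: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise ValueError(f"non-finite beta for {self.snp_id!r}")
        if self.se < 0 or not math.isfinite(self.se):
            raise ValueError(f"invalid standard error {self.se!r} for {self.snp_id!r}")


@dataclass
class CausalEstimate:
    """Pooled causal effect of an exposure gene on an outcome gene.

    ``beta_hat`` and ``se`` come from IVW pooling of per-instrument Wald
    ratios; ``z`` and ``p`` are filled by :func:`wald_test`.
    """

    exposure_gene: str
    outcome_gene: str
    beta_hat: float
    se: float
    n_ivs: int
    z: float = field(default=math.nan)
    p: float = field(default=math.nan)


def marginal_cis_effect(
    genotype: Sequence[float] | np.ndarray,
    expression: Sequence[float] | np.ndarray,
    snp_id: str = "snp",
) -> CisEffect:
    """Univariate OLS of expression on allele count, with intercept.

    Returns the slope and its standard error; these (beta, se) pairs are the
    atoms the IVW estimator pools.

    Raises
    ------
    DegenerateInstrumentError
        If the genotype vector is constant (monomorphic in the sample).
    ValueError
        On length mismatch or fewer than 3 samples.
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(expression, dtype=float)
    if g.ndim != 1 or y.ndim != 1:
        raise ValueError("genotype and expression must be 1-D vectors")
    if g.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {g.shape[0]} genotypes vs {y.shape[0]} expression values")
    n = g.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")

    gc = g - g.mean()
    sxx = float(gc @ gc)
    if sxx == 0.0:
        raise DegenerateInstrumentError(f"constant genotype for {snp_id!r}")

    yc = y - y.mean()
    beta = float(gc @ yc) / sxx
    # residual sum of squares of the fitted line, via the identity
    # RSS = Syy - beta^2 * Sxx (guard tiny negative from cancellation)
    rss = max(float(yc @ yc) - beta * beta * sxx, 0.0)
    se = math.sqrt(rss / (n - 2) / sxx)
    return CisEffect(snp_id=snp_id, beta=beta, se=se, n=n)


def wald_ratio(exposure_effect: CisEffect, outcome_effect: CisEffect) -> float:
    """Single-instrument causal estimate: outcome beta over exposure beta."""
    if exposure_effect.beta == 0.0:
        raise DegenerateInstrumentError(
            f"exposure effect of {exposure_effect.snp_id!r} is exactly 0; Wald ratio undefined"
        )
    return outcome_effect.beta / exposure_effect.beta


def ivw_estimate(
    exposure_effects: Sequence[CisEffect],
    outcome_effects: Sequence[CisEffect],
    exposure_gene: str = "exposure",
    outcome_gene: str = "outcome",
) -> CausalEstimate:
    """Inverse-variance weighted pooling of per-instrument effects.

    With instruments k = 1..K, exposure-side slopes b_x[k], outcome-side
    slopes b_y[k] and outcome-side standard errors s[k]:

        beta_hat = sum(b_x b_y / s^2) / sum(b_x^2 / s^2)
        se       = sqrt(1 / sum(b_x^2 / s^2))

    Equivalent to a zero-intercept weighted least-squares fit of b_y on b_x
    with weights 1/s^2. With a single instrument it collapses to the Wald
    ratio. The Wald statistic and p-value are filled in via
    :func:`wald_test`.
    """
    if len(exposure_effects) == 0:
        raise ValueError("no instruments supplied")
    if len(exposure_effects) != len(outcome_effects):
        raise ValueError("exposure and outcome effect lists differ in length")
    for ex, out in zip(exposure_effects, outcome_effects):
        if ex.snp_id != out.snp_id:
            raise ValueError(f"misaligned SNP ids: {ex.snp_id!r} vs {out.snp_id!r}")

    bx = np.array([e.beta for e in exposure_effects])
    by = np.array([e.beta for e in outcome_effects])
    s = np.array([e.se for e in outcome_effects])
    if np.any(s <= 0):
        raise ValueError("all outcome-side standard errors must be > 0")

    w = s**-2.0
    denom = float(bx * bx @ w)
    if denom == 0.0:
        raise DegenerateInstrumentError("all exposure effects are zero; IVW denominator degenerate")
    if len(exposure_effects) == 1:
        beta_hat = float(by[0] / bx[0])  # exact Wald-ratio collapse
    else:
        beta_hat = float(bx * by @ w) / denom
    se = math.sqrt(1.0 / denom)
    est = CausalEstimate(
        exposure_gene=exposure_gene,
        outcome_gene=outcome_gene,
        beta_hat=beta_hat,
        se=se,
        n_ivs=len(exposure_effects),
    )
    wald_test(est)
    return est


def wald_test(estimate: CausalEstimate) -> float:
    """Two-sided Wald test of the pooled causal effect against zero.

    Uses the standard normal reference (the usual IVW asymptotics). Fills
    ``estimate.z`` and ``estimate.p`` in place and returns the p-value.
    """
    if estimate.se <= 0:
        raise ValueError(f"standard error must be > 0 for the Wald test, got {estimate.se}")
    z = estimate.beta_hat / estimate.se
    p = 2.0 * stats.norm.sf(abs(z))
    estimate.z = float(z)
    estimate.p = float(p)
    return estimate.p
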