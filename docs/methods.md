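# Methods

## Model and procedure

`mrggi` infers directed gene–gene interactions by one-sample Mendelian
randomization. For an ordered pair (exposure gene g_i, outcome gene g_j),
the instruments are independent cis-SNPs of g_i. For each instrument k the
package fits two univariate OLS regressions with intercept on the same
cohort — expression of g_i on allele count (exposure effect β̂_zx,k) and
expression of g_j on allele count (outcome effect β̂_zy,k with standard
error se_k) — and pools the per-instrument Wald ratios by inverse-variance
weighting:

    β̂ = Σ β̂_zx,k β̂_zy,k se_k⁻² / Σ β̂_zx,k² se_k⁻²,   se(β̂) = (Σ β̂_zx,k² se_k⁻²)^(−1/2)

This is algebraically the zero-intercept weighted least-squares slope of
outcome effects on exposure effects with weights se⁻², and with one
instrument it reduces to the Wald ratio (implemented exactly as β̂_zy/β̂_zx
in that case). Significance uses the Wald statistic z = β̂/se against the
standard normal — the usual fixed-effect IVW asymptotics; no Student-t
correction, since the instrument-level effects are estimated on large n
and the simulation calibration below confirms the normal reference holds.

The pair-level procedure:

1. **Candidate pairs.** Unordered pairs whose standardized-expression
   Pearson correlation exceeds a threshold strictly (default 0.75 for
   dense eQTL panels; 0.5 for sparser benchmark data). Testing every pair
   is both wasteful and multiplicity-punitive; uncorrelated pairs cannot
   carry a detectable causal effect of relevant size.
2. **Pleiotropy guard.** Pairs whose instrument sets share a SNP id are
   excluded: a variant that is cis to both genes can affect the outcome
   without passing through the exposure, violating the exclusion
   restriction.
3. **Bidirectional testing.** i → j uses g_i's instruments, j → i uses
   g_j's. A gene with an empty instrument set contributes no test in its
   exposure direction; that direction is treated as non-significant.
4. **Multiplicity.** Bonferroni over m = the number of directional tests
   actually performed (each direction is its own hypothesis; m is not the
   pair count).
5. **Classification.** With adjusted p-values and level α (default 0.05,
   strict inequality): both significant → bidirectional; one → that
   direction; neither → independent.

Assumptions inherited from MR: instruments are associated with the
exposure gene (relevance — enforced by selection), independent of
confounders (randomized at meiosis), and affect the outcome only through
the exposure (exclusion — partially protected by the pleiotropy guard and
by using *independent* cis variants). An invalid instrument, e.g. one in
LD with a cis variant of the outcome gene, can still bias a call.

## Instrument selection

- **Cis window**: variants within ±1 Mb of the gene's TSS, closed
  interval, 1-based coordinates (BED-like 0-based input is converted on
  read).
- **Independent-variant selection**: forward-stepwise conditional
  selection. At each step the candidate with the smallest conditional
  p-value — computed by Frisch–Waugh–Lovell residualization against the
  already-selected variants, Student-t reference with df = n − 2 − |selected| —
  enters, until no candidate has conditional p < `p_enter` (default 1e-3)
  or `max_ivs` (default 10) is reached. Collinear candidates (residual
  variance numerically zero, e.g. perfect-LD duplicates) are skipped.
  Defaults are deliberately conservative: instruments must carry clearly
  non-redundant signal. The selector is pluggable — any callable mapping
  (genotypes, expression) to an instrument set can replace it, e.g. an
  external fine-mapper; the MR core only requires that the selected
  variants be mutually independent.
- The reported per-instrument effects are the **marginal** univariate
  slopes of the selected SNPs (these, not conditional effects, are what
  the IVW formula consumes).
- **MAF floor** 0.01 before selection: near-monomorphic variants give
  unstable OLS standard errors.
- **Weak-instrument filter** (optional, default off; 0.2 when emulating
  sparse-genotype benchmarks): drops instruments with |marginal effect| <
  threshold on standardized data; the boundary value is kept.
- **Top-k filter**: largest |effect| first, ties broken by SNP id for
  determinism.

## Synthetic data

The two-gene generative model (the simulator's default study conditions):

    g1 = S1 β1ᵀ + u1 + e1
    g2 = S2 β2ᵀ + β_causal · g1 + u2 + e2

with S ~ Binomial(2, MAF = 0.3) additively coded, residuals e ~ N(0,1),
and optional confounders (u1, u2) ~ MVN(0, [[1, ρ],[ρ, 1]]) drawn via the
exact Cholesky construction u2 = ρ·a + √(1−ρ²)·b. Cis-effect sets used by
the study runners: one instrument {0.6}; three {0.55, 0.4, 0.25}; five
{0.55, 0.4, 0.35, 0.3, 0.25}; weak-instrument variants {0.4, 0.3, 0.1},
{0.4, 0.1, 0.1}, {0.1, 0.1, 0.1} (0.1 being the "weak" effect size).
Causal-effect grid ±{0.7, 0.5, 0.3, 0.15, 0.05, 0.025, 0}; ρ grid
±{0.9, 0.5, 0.2} and 0.

**Sample size.** n = 1000 per replicate, the scale of a large segregant
panel (≈ 10³ lines). Null calibration is insensitive to n; power curves
are functions of it and are always reported with their n.

**Seeding.** One integer seed streams every replicate through
`SeedSequence(entropy=seed, spawn_key=(stream, replicate))`, so any single
replicate can be regenerated in isolation and full tables are bit-for-bit
reproducible.

**Common random numbers.** Within one power-study call, every grid cell
(β, and ρ or instrument count) replays the same per-replicate substream.
Differences along a power curve therefore reflect the parameter change,
not independent sampling noise — the standard paired design for comparing
points on simulated operating-characteristic curves. The FPR runners use
independent substreams per cell, since their cells are compared to
external reference values, not to each other.

**The many-gene simulator** composes the pair model along a user-supplied
DAG: each gene gets private cis-SNPs placed near its own TSS (genes spaced
10 Mb apart so cis windows never overlap), and expression is generated in
topological order. It emulates: additive cis genetics, linear regulatory
propagation, Gaussian noise, genome positions for window logic. It does
**not** emulate: LD between variants, trans-eQTLs, shared (pleiotropic)
cis variants, non-linear or cell-state-dependent regulation, count noise,
or realistic expression distributions. Passing tests on this generator
therefore demonstrate correctness of the estimator and pipeline under the
model's own assumptions — not robustness to the full messiness of real
expression data.

## Study runners and their checks

- **Null calibration** (β_causal = 0): the false-positive rate is counted
  per *directional* test — the fraction of replicates where the g1 → g2
  unadjusted Wald p falls below the cutoff. (Counting a pair as a false
  positive if *either* direction rejects would sit near 2α and is not what
  a per-test calibration claim means.) At 10,000 replicates the acceptance
  checks use a 3-binomial-SE band around the reference value.
- **Power**: fraction of replicates with unadjusted p < 0.05 in the causal
  direction; 1,000 replicates per cell. Monotonicity checks (power
  nondecreasing in |β|; more instruments, more power) are asserted up to
  3 SE of the paired difference of two empirical proportions: near β = 0
  the true power difference is second-order (≈ 5·10⁻⁴ for the 0 → 0.025
  step) and far below binomial noise, so a literal every-cell inequality
  would fail a correct implementation by coin flip.
- **Known property — power is not exactly ρ-invariant.** Because u2
  correlates with g1 through u1, var(g2) contains a 2·β·ρ term, so the
  outcome-side standard errors — and hence power on the steep part of the
  curve — genuinely decrease as ρ runs from +0.9 to −0.9 (for β > 0). At
  n = 1000 the cross-ρ spread reaches ≈ 0.1–0.17 around β = 0.3. The
  estimator itself stays unbiased (mean IVW estimate within 0.03 of the
  truth at β = 0.3, ρ = 0.5); only its precision varies with ρ.
- The simulation runners instrument with the *true* simulated SNPs
  (top-k by |true effect| where a count sweep is requested); real-data
  runs go through the selection stack. The fast array path used inside
  the replicate loops (`directional_ivw_z`) is tested for exact agreement
  with the object-level `marginal_cis_effect` + `ivw_estimate` route.

## Evaluation

Directed precision, recall and F1 against a gold-standard edge list. A
predicted a → b earns no credit for a gold b → a: direction is the point
of the method, and an undirected match metric would flatter the
correlation baseline. The baseline (`correlation_baseline`) emits every
super-threshold pair in both directions; on a 20-gene causal chain it
caps near precision 0.5 while the causal pipeline recovers directions,
which is the comparison the benchmark harness property-tests. The
single-genotype-per-gene reader (`read_dream5`) treats each gene's
genotype variable as its one-element instrument set; expression and
genotypes are standardized per feature (population variance, denominator
n, so rows are exactly unit-variance) before analysis.

## Numerical and design notes

- Marginal OLS uses the closed form with RSS = Syy − β²Sxx, guarded
  against tiny negative cancellation; se = 0 arises only for noiseless
  degenerate input, and the Wald test rejects se ≤ 0 rather than
  returning p = 0.
- Regressions keep an intercept even on standardized data (harmless, and
  robust to unstandardized input).
- One-sample design: exposure- and outcome-side effects come from the same
  cohort, with no overlapping-sample correction.
- Louvain clustering runs on the undirected, unweighted projection
  (parallel arcs collapsed), resolution 1.0, explicit seed; labels are
  contiguous from 1 in decreasing community-size order. Degree centrality
  is in+out degree on the directed multigraph, so the two arcs of a
  bidirectional call both count; hub filtering keeps degree ≥ 3 by
  default.
- Tie-breaks everywhere (instrument ordering, label ordering, edge-table
  sorting) are lexical, making every output byte-reproducible for a fixed
  seed.

## Limitations

- Stepwise conditional selection is a pragmatic stand-in for posterior
  fine-mapping; in strong-LD regions it can pick a tag rather than the
  causal variant. The selector interface exists precisely so a
  fine-mapping tool can be swapped in.
- No robust-MR variants (Egger regression, weighted median, multivariable
  MR); invalid instruments that slip past the pleiotropy guard bias
  estimates.
- Mediated effects are real causal effects: in a chain a → b → c the
  a → c test can legitimately reject if corr(a, c) clears the candidate
  threshold. Against a direct-edge gold standard those calls count as
  false positives.
- Genotype input is an allele-count TSV; VCF/PLINK parsing is out of
  scope for this version.
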