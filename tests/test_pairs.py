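"""Pair-level inference: candidates, pleiotropy, bidirectional tests, calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrggi import test_pair as mr_test_pair
from mrggi import (
    GenePair,
    IVSet,
    CisEffect,
    SimulationConfig,
    bonferroni_adjust,
    candidate_pairs,
    classify_interaction,
    directional_ivw_z,
    infer_interactions,
    ivw_estimate,
    marginal_cis_effect,
    pleiotropy_filter,
    simulate_pair,
)


def _expr_frame(X, genes=None):
    genes = genes or [f"g{i + 1}" for i in range(X.shape[0])]
    return pd.DataFrame(X, index=genes)


class TestCandidatePairs:
    def test_identical_rows_always_pair(self, rng):
        x = rng.standard_normal(50)
        pairs = candidate_pairs(_expr_frame(np.vstack([x, x])), 0.95)
        assert len(pairs) == 1 and pairs[0].correlation == pytest.approx(1.0)

    def test_independent_rows_excluded(self, rng):
        X = rng.standard_normal((2, 1000))
        assert candidate_pairs(_expr_frame(X), 0.5) == []

    def test_matches_brute_force_scan(self, rng):
        """Shared-factor construction checked against an all-pairs corrcoef scan."""
        z = rng.standard_normal(300)
        X = np.vstack([
            z + 0.1 * rng.standard_normal(300),
            z + 0.5 * rng.standard_normal(300),
            z + 2.0 * rng.standard_normal(300),
            rng.standard_normal(300),
        ])
        frame = _expr_frame(X)
        got = {(p.gene_i, p.gene_j) for p in candidate_pairs(frame, 0.5)}
        R = np.corrcoef(X)
        expected = {
            tuple(sorted((f"g{a + 1}", f"g{b + 1}")))
            for a, b in itertools.combinations(range(4), 2)
            if abs(R[a, b]) > 0.5
        }
        assert got == expected
        assert expected  # construction must produce at least one pair

    def test_constant_row_excluded(self, rng):
        X = np.vstack([np.ones(50), rng.standard_normal(50)])
        assert candidate_pairs(_expr_frame(X), 0.5) == []


def _iv(gene, snps):
    effects = [CisEffect(s, 0.5, 0.05, 100) for s in snps]
    return IVSet(gene, list(snps), effects)


class TestPleiotropyFilter:
    def test_shared_snp_removed(self):
        pair = GenePair.make("a", "b", 0.8)
        iv_map = {"a": _iv("a", ["s1", "s2"]), "b": _iv("b", ["s2", "s3"])}
        assert pleiotropy_filter([pair], iv_map) == []

    def test_disjoint_kept(self):
        pair = GenePair.make("a", "b", 0.8)
        iv_map = {"a": _iv("a", ["s1"]), "b": _iv("b", ["s2"])}
        assert pleiotropy_filter([pair], iv_map) == [pair]

    def test_matches_set_intersection_oracle(self, rng):
        snp_pool = [f"s{i}" for i in range(30)]
        pairs, iv_map = [], {}
        for i in range(100):
            gi, gj = f"a{i:03d}", f"b{i:03d}"
            iv_map[gi] = _iv(gi, list(rng.choice(snp_pool, 3, replace=False)))
            iv_map[gj] = _iv(gj, list(rng.choice(snp_pool, 3, replace=False)))
            pairs.append(GenePair.make(gi, gj, 0.9))
        got = pleiotropy_filter(pairs, iv_map)
        expected = [
            p for p in pairs
            if not set(iv_map[p.gene_i].snp_ids) & set(iv_map[p.gene_j].snp_ids)
        ]
        assert got == expected


def _pair_frames(data):
    """SimulatedDataset -> (expression, genotypes, iv_map) for test_pair."""
    n1 = data.genotypes_g1.shape[1]
    n2 = data.genotypes_g2.shape[1]
    snps1 = [f"g1_s{k}" for k in range(n1)]
    snps2 = [f"g2_s{k}" for k in range(n2)]
    expression = pd.DataFrame(np.vstack([data.g1, data.g2]), index=["g1", "g2"])
    genotypes = pd.DataFrame(
        np.vstack([data.genotypes_g1.T, data.genotypes_g2.T]), index=snps1 + snps2
    )
    iv_map = {}
    for gene, snps, S, y in (
        ("g1", snps1, data.genotypes_g1, data.g1),
        ("g2", snps2, data.genotypes_g2, data.g2),
    ):
        effects = [marginal_cis_effect(S[:, k], y, snp_id=s) for k, s in enumerate(snps)]
        effects.sort(key=lambda e: -abs(e.beta))
        iv_map[gene] = IVSet(gene, [e.snp_id for e in effects], effects)
    return expression, genotypes, iv_map


class TestTestPair:
    def test_parameter_recovery(self):
        """Mean forward estimate over 500 replicates near the true effect 0.5."""
        estimates = []
        for rep in range(500):
            config = SimulationConfig(beta_g1g2=0.5, seed=0)
            data = simulate_pair(config, rng=np.random.default_rng(50_000 + rep))
            expr, geno, iv_map = _pair_frames(data)
            est_ij, est_ji = mr_test_pair(GenePair.make("g1", "g2", 0.5), iv_map, geno, expr)
            estimates.append(est_ij.beta_hat)
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.05)

    def test_null_p_values_uniform(self):
        """Under beta = 0 the forward p-values are U(0,1) (KS at 0.01)."""
        ps = []
        for rep in range(2000):
            data = simulate_pair(
                SimulationConfig(beta_g1g2=0.0),
                rng=np.random.default_rng(60_000 + rep),
            )
            _, _, z = directional_ivw_z(data.genotypes_g1, data.g1, data.g2)
            ps.append(2 * stats.norm.sf(abs(z)))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_array_path_matches_object_path(self):
        """directional_ivw_z agrees with marginal_cis_effect + ivw_estimate."""
        data = simulate_pair(SimulationConfig(beta_g1g2=0.3, seed=7))
        exp_eff = [
            marginal_cis_effect(data.genotypes_g1[:, k], data.g1, snp_id=f"s{k}")
            for k in range(3)
        ]
        out_eff = [
            marginal_cis_effect(data.genotypes_g1[:, k], data.g2, snp_id=f"s{k}")
            for k in range(3)
        ]
        est = ivw_estimate(exp_eff, out_eff)
        beta_hat, se, z = directional_ivw_z(data.genotypes_g1, data.g1, data.g2)
        assert beta_hat == pytest.approx(est.beta_hat, abs=1e-12)
        assert se == pytest.approx(est.se, abs=1e-12)
        assert z == pytest.approx(est.z, abs=1e-10)

    def test_empty_ivset_direction_absent(self):
        data = simulate_pair(SimulationConfig(beta_g1g2=0.5, seed=3))
        expr, geno, iv_map = _pair_frames(data)
        iv_map["g2"] = IVSet("g2")
        est_ij, est_ji = mr_test_pair(GenePair.make("g1", "g2", 0.5), iv_map, geno, expr)
        assert est_ij is not None and est_ji is None


class TestAdjustAndClassify:
    def test_bonferroni(self):
        assert bonferroni_adjust([0.01], 10) == [pytest.approx(0.1)]
        assert bonferroni_adjust([0.5], 10) == [1.0]
        assert bonferroni_adjust([0.01, 0.5], 10) == [pytest.approx(0.1), 1.0]

    def test_bonferroni_m_too_small_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], 1)

    @pytest.mark.parametrize(
        "p_ij, p_ji, expected",
        [
            (0.001, 0.8, "i_to_j"),
            (0.8, 0.001, "j_to_i"),
            (0.01, 0.01, "bidirectional"),
            (0.5, 0.9, "independent"),
            (0.05, 0.05, "independent"),  # strict inequality at the boundary
            (None, 0.01, "j_to_i"),
            (None, None, "independent"),
        ],
    )
    def test_truth_table(self, p_ij, p_ji, expected):
        assert classify_interaction(p_ij, p_ji, alpha=0.05) == expected

    def test_relabeling_swaps_directed_scenarios(self):
        """Swapping the two genes of a pair swaps i_to_j <-> j_to_i."""
        swap = {"i_to_j": "j_to_i", "j_to_i": "i_to_j",
                "independent": "independent", "bidirectional": "bidirectional"}
        for p_ij, p_ji in [(0.001, 0.8), (0.8, 0.001), (0.01, 0.02), (0.5, 0.5)]:
            assert classify_interaction(p_ji, p_ij) == swap[classify_interaction(p_ij, p_ji)]


class TestInferInteractions:
    def test_funnel_counts_monotone(self, three_edge_network):
        data = three_edge_network
        from mrggi.pipeline import select_all_ivs, RunConfig, standardize
        import tempfile

        expr = standardize(data["expression"])
        from mrggi import select_independent_ivs

        iv_map = {}
        for gene in expr.index:
            snps = [s for s in data["genotypes"].index if s.startswith(gene)]
            iv_map[gene] = select_independent_ivs(
                data["genotypes"].loc[snps], expr.loc[gene].to_numpy(), gene_id=gene
            )
        counts = {}
        calls = infer_interactions(expr, data["genotypes"], iv_map, 0.5, counts=counts)
        assert counts["candidate_pairs"] >= counts["pairs_after_pleiotropy"]
        assert counts["pairs_after_pleiotropy"] >= counts["non_independent_calls"]
        assert counts["directional_tests"] <= 2 * counts["pairs_after_pleiotropy"]
        assert {c.scenario for c in calls} <= {"independent", "i_to_j", "j_to_i", "bidirectional"}
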