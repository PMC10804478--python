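"""Rank-sum and Spearman tests against brute-force enumeration oracles,
plus the association/stratification/concordance screens."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from timehom import SimConfig, simulate_cohort, quantify_cohort
from timehom.panel import DEFAULT_PANEL
from timehom.stats import (
    association_screen,
    modality_concordance,
    rank_sum_test,
    spearman_corr,
    tls_stratified_compare,
)


def ranksum_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating every group labeling (tie-free)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mid = n1 * len(b) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        count += abs(u - mid) >= abs(u_obs - mid) - 1e-9
        total += 1
    return u_obs, count / total


class TestRankSum:
    def test_fully_separated_small_groups(self):
        # {1,2} vs {3,4}: U = 0; 2 of the 6 labelings are as extreme
        res = rank_sum_test([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_statistic_at_null_midpoint_gives_p_one(self):
        # U equals n1*n2/2 exactly, so every labeling is at least as
        # extreme: the exact two-sided p is 1 by symmetry
        res = rank_sum_test([1, 4], [2, 3])
        assert res.statistic == pytest.approx(2.0)
        assert res.p_value == pytest.approx(1.0)

    def test_six_vs_six_matches_full_enumeration(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(size=6), rng.normal(1.0, 1.0, size=6)
        res = rank_sum_test(a, b)
        u, p = ranksum_enumeration_oracle(a, b)
        assert res.statistic == pytest.approx(u)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_every_small_size_combination_matches_enumeration(self):
        rng = np.random.default_rng(22)
        for n1 in range(1, 12):
            for n2 in range(1, 13 - n1):
                a, b = rng.normal(size=n1), rng.normal(size=n2)
                res = rank_sum_test(a, b)
                assert res.method == "exact"
                _, p = ranksum_enumeration_oracle(a, b)
                assert res.p_value == pytest.approx(p, abs=1e-12), (n1, n2)

    def test_exact_and_asymptotic_agree_at_moderate_n(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            a, b = rng.normal(size=10), rng.normal(size=10)
            p_exact = rank_sum_test(a, b, method="exact").p_value
            p_asym = rank_sum_test(a, b, method="asymptotic").p_value
            assert abs(p_exact - p_asym) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_invariant_to_sample_ordering(self):
        rng = np.random.default_rng(24)
        a, b = rng.normal(size=9), rng.normal(size=7)
        r1 = rank_sum_test(a, b)
        r2 = rank_sum_test(a[::-1], np.random.default_rng(0).permutation(b))
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value


class TestSpearman:
    def test_perfect_monotone_association(self):
        x = [1, 2, 3, 4, 5, 6]
        assert spearman_corr(x, [10, 20, 25, 30, 44, 50]).statistic == pytest.approx(1.0)
        assert spearman_corr(x, [50, 44, 30, 25, 20, 10]).statistic == pytest.approx(-1.0)

    def test_exact_p_for_monotone_n6(self):
        # only the 2 extreme permutations of 720 reach |rho| = 1
        res = spearman_corr([1, 2, 3, 4, 5, 6], [2, 3, 5, 7, 11, 13])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 720)

    def test_midrank_handling_with_ties_matches_hand_ranking(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]  # midranks (1, 2.5, 2.5, 4, 5)
        y = [5.0, 1.0, 4.0, 2.0, 3.0]
        res = spearman_corr(x, y)
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert res.statistic == pytest.approx(oracle)
        assert res.statistic == pytest.approx(sps.spearmanr(x, y).statistic)

    def test_t_approximation_matches_scipy_at_larger_n(self):
        rng = np.random.default_rng(25)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman_corr(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 2], [3, 4])


class TestAssociationScreen:
    def _screen(self, seed, diameter_effect=-0.08):
        from timehom.simulate import CovariateEffects

        cfg = SimConfig(
            n_tumors=20,
            seed=seed,
            n_filler_genes=0,
            covariate_effects=CovariateEffects(diameter=diameter_effect),
        )
        b = simulate_cohort(cfg)
        samples = quantify_cohort(b.ihc_fields, b.tls)
        feats = samples[["tumor_id"]].copy()
        for m in DEFAULT_PANEL.markers:
            feats[m] = samples[f"{m}_density"]
        return association_screen(feats, b.clinicopath.rename(columns={})), b

    def test_configured_negative_diameter_effect_recovered(self):
        negatives = 0
        for seed in range(10):
            screen, _ = self._screen(seed)
            row = screen.query("feature == 'CD4' and covariate == 'max_diameter'")
            negatives += float(row["statistic"].iloc[0]) < 0
        assert negatives >= 9

    def test_raw_p_reported_alongside_bh_q(self):
        screen, _ = self._screen(0)
        ok = screen["computable"]
        assert (screen.loc[ok, "q_value"] >= screen.loc[ok, "p_value"] - 1e-12).all()

    def test_unmatched_tumor_ids_rejected(self):
        screen, b = self._screen(1)
        samples = quantify_cohort(b.ihc_fields, b.tls)
        feats = samples[["tumor_id"]].assign(CD4=samples["CD4_density"])
        clin = b.clinicopath[b.clinicopath["case_id"] != "case01"]
        with pytest.raises(ValueError, match="case01"):
            association_screen(feats, clin)

    def test_permuted_labels_give_uniform_p(self):
        # under label permutation the rank-sum p-values are uniform
        rng = np.random.default_rng(26)
        values = rng.normal(size=50)
        ps = []
        for _ in range(300):
            labels = rng.permutation(np.repeat([0, 1], 25))
            ps.append(rank_sum_test(values[labels == 0], values[labels == 1]).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestTlsStratification:
    def test_coupled_generator_raises_cd4_in_tls_positive_sections(self):
        higher = 0
        for seed in range(5):
            b = simulate_cohort(SimConfig(n_tumors=15, seed=seed, n_filler_genes=0))
            samples = quantify_cohort(b.ihc_fields, b.tls)
            cmp = tls_stratified_compare(samples, DEFAULT_PANEL.markers)
            row = cmp[cmp["feature"] == "CD4"].iloc[0]
            higher += row["median_positive"] > row["median_negative"]
        assert higher >= 4

    def test_uncoupled_generator_keeps_type1_rate_nominal(self):
        sig = total = 0
        for seed in range(120):
            cfg = SimConfig(
                n_tumors=6, seed=seed, n_filler_genes=0, tls_coupling=0.0
            )
            b = simulate_cohort(cfg)
            samples = quantify_cohort(b.ihc_fields, b.tls)
            cmp = tls_stratified_compare(samples, ["CD4"])
            row = cmp.iloc[0]
            if row["computable"]:
                sig += row["p_value"] < 0.05
                total += 1
        assert total > 80
        assert 0.01 <= sig / total <= 0.11

    def test_empty_stratum_flagged_not_computable(self):
        b = simulate_cohort(SimConfig(n_tumors=3, seed=2, n_filler_genes=0, tls_rate=0.0))
        samples = quantify_cohort(b.ihc_fields, b.tls)
        samples["tls_count"] = 0
        cmp = tls_stratified_compare(samples, ["CD4"])
        assert not cmp.iloc[0]["computable"]

    def test_pdl1_stratification_excludes_pdl1_itself(self, small_samples):
        cmp = tls_stratified_compare(small_samples, DEFAULT_PANEL.markers, stratify_by="pdl1")
        assert "PD-L1" not in set(cmp["feature"])


class TestModalityConcordance:
    def _features(self, arr):
        from timehom.similarity import FeatureMatrix

        n = arr.shape[0]
        idx = pd.MultiIndex.from_arrays(
            [np.repeat([f"t{i}" for i in range(n // 5)], 5), np.tile(list("ABCDE"), n // 5)],
            names=["tumor_id", "region"],
        )
        cols = [f"f{k}" for k in range(arr.shape[1])]
        return FeatureMatrix(pd.DataFrame(arr, index=idx, columns=cols))

    def test_identical_matrices_fully_concordant(self):
        rng = np.random.default_rng(27)
        X = self._features(rng.normal(size=(25, 3)))
        from timehom.similarity import analyze_cohort

        res = analyze_cohort(X, lomo=False)
        rep = modality_concordance(X, X, res, res)
        assert all(v["rho"] == pytest.approx(1.0) for v in rep["per_feature"].values())
        assert rep["classification_agreement"]["agreement_fraction"] == 1.0

    def test_independent_noise_has_near_zero_mean_rho(self):
        rng = np.random.default_rng(28)
        rhos = []
        for _ in range(20):
            a = self._features(rng.normal(size=(25, 2)))
            b = self._features(rng.normal(size=(25, 2)))
            rep = modality_concordance(a, b)
            rhos.extend(v["rho"] for v in rep["per_feature"].values())
        assert abs(np.mean(rhos)) < 0.1

    def test_default_generator_coupling_gives_positive_median_rho(self, small_bundle):
        from timehom.rna import default_gene_sets, gene_set_abundance, normalize_counts
        from timehom.similarity import assemble_features

        samples = quantify_cohort(small_bundle.ihc_fields, small_bundle.tls)
        X_ihc = assemble_features(samples, DEFAULT_PANEL, "ihc")
        ab = gene_set_abundance(
            normalize_counts(small_bundle.expression), default_gene_sets()
        )
        X_rna = assemble_features(ab.data, DEFAULT_PANEL, "rna")
        rep = modality_concordance(X_ihc, X_rna)
        assert rep["median_rho"] > 0
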