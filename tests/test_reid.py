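"""Re-identification likelihood model: site likelihoods, moments, pruning,
cohort synthesis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hostguard.reid import (
    GenotypePanel,
    ReidConfig,
    attrition_experiment,
    bonferroni_thresholds,
    expected_score,
    hwe_probs,
    ld_prune,
    likelihood_score,
    reidentify,
    site_likelihood,
    site_log_likelihood,
    standardized_pvalue,
    synthesize_cohort,
    variance_score,
)

EPS = 1e-6


class TestSiteLikelihood:
    def test_heterozygote_is_half_per_read(self):
        # g=1 makes both brackets 1, so L = 2^-n independent of k and eps
        for n in (1, 4, 9):
            for k in range(n + 1):
                assert site_likelihood(1, n, k, EPS) == pytest.approx(0.5**n, rel=1e-12)
        assert site_likelihood(1, 4, 2, EPS) == pytest.approx(0.0625)

    def test_homozygous_reference_all_ref_reads(self):
        assert site_likelihood(0, 3, 3, EPS) == pytest.approx((1 - EPS) ** 3, rel=1e-12)

    def test_homozygous_alt_with_ref_reads_requires_errors(self):
        assert site_likelihood(2, 2, 2, EPS) == pytest.approx(EPS**2, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            site_log_likelihood(3, 2, 1)
        with pytest.raises(ValueError):
            site_log_likelihood(1, 2, 3)


class TestLikelihoodScore:
    def test_all_heterozygous_identity(self):
        n = np.array([3, 1, 7])
        k = np.array([0, 1, 4])
        ls = likelihood_score([1, 1, 1], n, k, EPS)
        assert ls == pytest.approx(-np.log(2) * n.sum(), rel=1e-12)

    def test_single_site_near_zero(self):
        assert likelihood_score([0], [1], [1], EPS) == pytest.approx(np.log(1 - EPS))

    def test_matches_product_then_log_oracle(self):
        # few sites with shallow coverage keep the naive product above
        # the float underflow limit
        rng = np.random.default_rng(31)
        g = rng.integers(0, 3, size=20)
        n = rng.integers(1, 3, size=20)
        k = np.array([rng.integers(0, ni + 1) for ni in n])
        naive = np.log(np.prod([site_likelihood(gi, ni, ki, EPS) for gi, ni, ki in zip(g, n, k)]))
        assert likelihood_score(g, n, k, EPS) == pytest.approx(naive, abs=1e-9)

    def test_missing_genotypes_skipped_and_all_missing_rejected(self):
        ls = likelihood_score([1, -1], [2, 5], [1, 5], EPS)
        assert ls == pytest.approx(-2 * np.log(2))
        with pytest.raises(ValueError):
            likelihood_score([-1], [2], [1], EPS)


class TestHweProbs:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0, (1, 0, 0)), (0.5, (0.25, 0.5, 0.25)), (0.2, (0.64, 0.32, 0.04))],
    )
    def test_known_values(self, p, expected):
        assert hwe_probs(p) == pytest.approx(expected)

    def test_sums_to_one(self, rng):
        p = rng.random(100)
        assert np.stack(hwe_probs(p)).sum(axis=0) == pytest.approx(np.ones(100), abs=1e-12)


class TestPopulationMoments:
    def test_degenerate_population_reduces_to_single_genotype(self):
        e = expected_score([0.0], [3], [3], EPS)
        assert e == pytest.approx(site_log_likelihood(0, 3, 3, EPS))
        assert variance_score([0.0], [3], [3], EPS) == pytest.approx(0.0, abs=1e-18)

    def test_single_site_hand_computed(self):
        # p=0.5, n=1, k=1: 0.25 ln(1-eps) + 0.5 ln(1/2) + 0.25 ln(eps)
        e = expected_score([0.5], [1], [1], EPS)
        expected = 0.25 * np.log(1 - EPS) + 0.5 * np.log(0.5) + 0.25 * np.log(EPS)
        assert e == pytest.approx(expected, rel=1e-12)
        assert e == pytest.approx(-3.8004, abs=1e-4)
        branches = np.array([site_log_likelihood(g, 1, 1, EPS) for g in (0, 1, 2)])
        probs = np.array([0.25, 0.5, 0.25])
        v_hand = float((probs * (branches - e) ** 2).sum())
        assert variance_score([0.5], [1], [1], EPS) == pytest.approx(v_hand, rel=1e-12)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(414)
        p = rng.uniform(0.1, 0.9, size=8)
        n = rng.integers(1, 5, size=8)
        k = np.array([rng.integers(0, ni + 1) for ni in n])
        draws = 100_000
        p0, p1, _ = hwe_probs(p)
        u = rng.random((draws, 8))
        g = (u > p0).astype(int) + (u > p0 + p1).astype(int)
        logl = np.stack([site_log_likelihood(gg, n, k, EPS) for gg in (0, 1, 2)])
        samples = logl[g, np.arange(8)].sum(axis=1)
        e, v = expected_score(p, n, k, EPS), variance_score(p, n, k, EPS)
        assert e == pytest.approx(samples.mean(), abs=3 * samples.std() / np.sqrt(draws))
        assert v == pytest.approx(samples.var(), rel=0.05)


class TestStandardizedPvalue:
    def test_score_at_expectation_gives_half(self):
        z, p = standardized_pvalue(-5.0, -5.0, 2.0)
        assert (z, p) == (0.0, 0.5)

    def test_normal_quantile_identity(self):
        z, p = standardized_pvalue(1.959964 * np.sqrt(4.0), 0.0, 4.0)
        assert p == pytest.approx(0.025, abs=1e-6)

    def test_matches_erf_oracle(self, rng):
        from math import erf, sqrt

        for _ in range(50):
            ls, e, v = rng.normal(), rng.normal(), rng.uniform(0.5, 3)
            z, p = standardized_pvalue(ls, e, v)
            assert p == pytest.approx(0.5 * (1 - erf(z / sqrt(2))), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardized_pvalue(1.0, 0.0, 0.0)


class TestLdPrune:
    def test_duplicated_site_dropped(self):
        rng = np.random.default_rng(5)
        col = rng.integers(0, 3, size=(1, 40))
        geno = np.vstack([col, col, rng.integers(0, 3, size=(1, 40))])
        panel = GenotypePanel(["s0", "s1", "s2"], [f"p{i}" for i in range(40)], geno)
        kept = ld_prune(panel)
        assert "s0" in kept and "s1" not in kept

    def test_independent_sites_kept(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.2, 0.8, size=20)
        u = rng.random((20, 500))
        p0, p1, _ = hwe_probs(p)
        geno = (u > p0[:, None]).astype(int) + (u > (p0 + p1)[:, None]).astype(int)
        panel = GenotypePanel([f"s{i}" for i in range(20)], [f"p{i}" for i in range(500)], geno)
        assert len(ld_prune(panel)) == 20

    def test_kept_sites_satisfy_r2_bound_within_window(self):
        rng = np.random.default_rng(7)
        base = rng.integers(0, 3, size=(10, 60)).astype(float)
        # make correlated copies interleaved with independents
        noisy = np.clip(base + (rng.random(base.shape) < 0.1), 0, 2)
        geno = np.vstack([base, noisy]).astype(int)
        panel = GenotypePanel([f"s{i}" for i in range(20)], [f"p{i}" for i in range(60)], geno)
        kept = ld_prune(panel, window=20, step=10, r2_max=0.1)
        idx = {s: i for i, s in enumerate(panel.site_ids)}
        cols = panel.genotypes[[idx[s] for s in kept]].astype(float)
        if len(kept) > 1:
            corr = np.corrcoef(cols)
            off = corr[~np.eye(len(kept), dtype=bool)]
            assert (off**2 <= 0.1 + 1e-9).all()

    def test_empty_panel_and_single_sample_edge_cases(self):
        panel = GenotypePanel([], ["a", "b"], np.zeros((0, 2), dtype=int))
        assert ld_prune(panel) == []
        one = GenotypePanel(["s"], ["a"], np.array([[1]]))
        with pytest.raises(ValueError):
            ld_prune(one)


class TestBonferroni:
    def test_published_scale(self):
        pairwise, per_meta = bonferroni_thresholds(0.05, 343, 343)
        assert pairwise == pytest.approx(0.05 / 117_649)
        assert per_meta == pytest.approx(0.05 / 343)

    def test_single_pair(self):
        assert bonferroni_thresholds(0.05, 1, 1) == (0.05, 0.05)


class TestSynthesizeCohort:
    def test_heterozygous_sites_give_balanced_reads(self):
        panel, freqs, pileups, donors = synthesize_cohort(
            4, 4000, mean_depth=0.5, seed=99
        )
        ks, ns = [], []
        for meta_id, pileup in pileups.items():
            j = panel.sample_ids.index(donors[meta_id])
            idx = {s: i for i, s in enumerate(panel.site_ids)}
            for _, row in pileup.iterrows():
                if panel.genotypes[idx[row["site_id"]], j] == 1:
                    ks.append(row["k"])
                    ns.append(row["n"])
        frac = sum(ks) / sum(ns)
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(sum(ns))

    def test_deterministic_and_sparse(self):
        a = synthesize_cohort(3, 500, mean_depth=0.1, seed=1)
        b = synthesize_cohort(3, 500, mean_depth=0.1, seed=1)
        pd.testing.assert_frame_equal(a[2]["meta0"], b[2]["meta0"])
        # Poisson(0.1): ~90% of sites uncovered
        assert len(a[2]["meta0"]) < 100


class TestReidentify:
    def test_insufficient_reads_flagged(self):
        panel, freqs, pileups, _ = synthesize_cohort(3, 300, mean_depth=0.2, seed=2)
        pileups["meta0"] = pileups["meta0"].iloc[0:0]  # strip all coverage
        result = reidentify(panel, pileups, freqs)
        assert "meta0" in result.insufficient
        assert set(result.table["metagenome_id"]) == {"meta1", "meta2"}

    def test_attrition_retention_bounds(self):
        _, _, pileups, _ = synthesize_cohort(3, 300, mean_depth=0.5, seed=3)
        same = attrition_experiment(pileups, 1.0, seed=4)
        for meta_id in pileups:
            pd.testing.assert_frame_equal(
                pileups[meta_id].reset_index(drop=True), same[meta_id].reset_index(drop=True)
            )
        empty = attrition_experiment(pileups, 0.0, seed=5)
        assert all(len(p) == 0 for p in empty.values())

    def test_donor_outranks_non_donors(self):
        panel, freqs, pileups, donors = synthesize_cohort(8, 1200, mean_depth=0.3, seed=6)
        result = reidentify(panel, pileups, freqs)
        t = result.table
        best = t.loc[t.groupby("metagenome_id")["LS"].idxmax()]
        hits = sum(donors[m] == g for m, g in zip(best["metagenome_id"], best["genotype_id"]))
        assert hits >= 7  # at least 7 of 8 donors top-ranked
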