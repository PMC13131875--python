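"""Tests for the marginal-vs-conditional deviation scan."""

import numpy as np
import pandas as pd
import pytest

from epicohort.genotypes import GenotypeMatrix
from epicohort.gxe_scan import (
    ScanConfig,
    compute_pcs,
    deviation_scan,
    fit_full,
    fit_marginal,
    maf_filter,
    scan_pairs,
)


def make_genotypes(dosages):
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[1]
    meta = pd.DataFrame(
        {
            "id": [f"v{j:05d}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(100, 100 + m),
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "maf": np.minimum(dosages.mean(0) / 2, 1 - dosages.mean(0) / 2),
        }
    )
    return GenotypeMatrix(dosages, [f"S{i}" for i in range(len(dosages))], meta)


def simulate_pairs(n, n_variants, beta3_map, seed, maf=0.3, env_mean=1.0, env_sd=2.0):
    """Null/alternative scan data: Y linear in G, E, and selected G*E.

    The environment has a nonzero mean: the marginal-vs-conditional
    deviation of an interacting pair is beta3 * E[E], so a centered
    environment would carry no signal for the scan to find. Its spread
    is kept wide relative to the mean, otherwise G and G*E become
    nearly collinear and the conditional effect is poorly identified.
    """
    rng = np.random.default_rng(seed)
    d = rng.binomial(2, maf, size=(n, n_variants)).astype(np.int8)
    e = rng.normal(env_mean, env_sd, size=n)
    y = 0.1 * e + rng.normal(size=n)
    for j in range(n_variants):
        y = y + 0.1 * d[:, j]
    for j, b3 in beta3_map.items():
        y = y + b3 * d[:, j] * e
    return make_genotypes(d), pd.DataFrame({"env": e}), y


class TestMafFilter:
    def test_strict_boundary(self):
        # variant with exactly MAF 0.05 is dropped
        n = 100
        d = np.zeros((n, 2), dtype=np.int8)
        d[:10, 0] = 1  # p = 0.05 exactly
        d[:30, 1] = 1  # p = 0.15
        g = make_genotypes(d)
        mask = maf_filter(g, 0.05)
        assert mask.tolist() == [False, True]

    def test_monomorphic_dropped(self):
        g = make_genotypes(np.zeros((50, 1), dtype=np.int8))
        assert not maf_filter(g, 0.05).any()

    def test_hand_counted_toy(self):
        d = np.array([[0, 1, 2], [1, 1, 2], [0, 0, 2], [2, 1, 2]], dtype=np.int8)
        g = make_genotypes(d)
        p = d.mean(axis=0) / 2  # [0.375, 0.375, 1.0]
        expected = np.minimum(p, 1 - p) > 0.2
        np.testing.assert_array_equal(maf_filter(g, 0.2), expected)


class TestComputePcs:
    def test_population_separation(self):
        rng = np.random.default_rng(0)
        n, m = 300, 100
        freqs = np.where(np.arange(m) % 2 == 0, 0.1, 0.5)
        d1 = rng.binomial(2, freqs, size=(n // 2, m))
        d2 = rng.binomial(2, freqs[::-1], size=(n // 2, m))
        g = make_genotypes(np.vstack([d1, d2]).astype(np.int8))
        scores = compute_pcs(g, 2)
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        from sklearn.metrics import silhouette_score

        assert silhouette_score(scores[:, :1], labels) > 0.8

    def test_k_zero_empty(self):
        g = make_genotypes(np.random.default_rng(1).integers(0, 3, (20, 5), dtype=np.int8))
        assert compute_pcs(g, 0).shape == (20, 0)

    def test_orthogonal(self):
        g = make_genotypes(np.random.default_rng(2).integers(0, 3, (50, 20), dtype=np.int8))
        scores = compute_pcs(g, 3)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_k_exceeding_rank_errors(self):
        d = np.tile(np.array([[0], [1], [2]], dtype=np.int8), (1, 4))
        g = make_genotypes(d)
        with pytest.raises(ValueError, match="rank|polymorphic"):
            compute_pcs(g, 4)

    def test_sign_convention_deterministic(self):
        g = make_genotypes(np.random.default_rng(3).integers(0, 3, (40, 10), dtype=np.int8))
        a = compute_pcs(g, 2)
        b = compute_pcs(g, 2)
        np.testing.assert_array_equal(a, b)


class TestFitMarginal:
    def test_exact_noiseless(self):
        g = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        y = 0.3 * g
        a1, se = fit_marginal(y, g)
        assert a1 == pytest.approx(0.3, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_permuted_g_near_zero(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.3, size=5000).astype(float)
        y = 0.5 * g + rng.normal(size=5000)
        g_perm = rng.permutation(g)
        a1, se = fit_marginal(y, g_perm)
        assert abs(a1) < 3 * se + 0.05

    def test_constant_g_errors(self):
        with pytest.raises(ValueError, match="constant"):
            fit_marginal(np.ones(10), np.ones(10))

    def test_covariate_equal_to_g_collinear(self):
        g = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        with pytest.raises(np.linalg.LinAlgError):
            fit_marginal(np.ones(6), g, covariates=g[:, None])

    def test_agrees_with_lstsq_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(20, 60))
            g = rng.binomial(2, 0.4, size=n).astype(float)
            if np.ptp(g) == 0:
                continue
            cov = rng.normal(size=(n, 2))
            y = rng.normal(size=n)
            a1, _ = fit_marginal(y, g, cov)
            design = np.column_stack([np.ones(n), g, cov])
            beta_oracle = np.linalg.lstsq(design, y, rcond=None)[0]
            assert a1 == pytest.approx(beta_oracle[1], abs=1e-8)


class TestFitFull:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(6)
        n = 10000
        g = rng.binomial(2, 0.3, size=n).astype(float)
        e = rng.normal(size=n)
        y = 0.2 * g + 0.1 * e + 0.4 * g * e + rng.normal(size=n)
        fit = fit_full(y, g, e)
        for key, truth in (("b1", 0.2), ("b2", 0.1), ("b3", 0.4)):
            assert abs(fit[key] - truth) < 3 * fit[f"{key}_se"]

    def test_null_b3_t_statistic_standard_normal(self):
        rng = np.random.default_rng(7)
        tstats = []
        for _ in range(200):
            n = 300
            g = rng.binomial(2, 0.3, size=n).astype(float)
            e = rng.normal(size=n)
            y = 0.2 * g + 0.1 * e + rng.normal(size=n)
            fit = fit_full(y, g, e)
            tstats.append(fit["b3"] / fit["b3_se"])
        tstats = np.array(tstats)
        assert tstats.mean() == pytest.approx(0.0, abs=0.2)
        assert tstats.std() == pytest.approx(1.0, abs=0.15)

    def test_constant_e_errors(self):
        g = np.array([0.0, 1.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="environment"):
            fit_full(np.ones(4), g, np.zeros(4))

    def test_collinear_interaction_flagged(self):
        # E constant within dosage groups: E = 1{G==1}, so G*E == E and
        # only the interaction column is redundant (1, G, E has full rank)
        g = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0] * 10)
        e = (g == 1).astype(float)
        y = np.arange(60, dtype=float)
        fit = fit_full(y, g, e)
        assert fit["collinear_interaction"]
        assert np.isnan(fit["b3"])
        assert np.isfinite(fit["b1"])

    def test_agrees_with_lstsq_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(30, 80))
            g = rng.binomial(2, 0.4, size=n).astype(float)
            e = rng.normal(size=n)
            if np.ptp(g) == 0:
                continue
            y = rng.normal(size=n)
            fit = fit_full(y, g, e)
            design = np.column_stack([np.ones(n), g, e, g * e])
            oracle = np.linalg.lstsq(design, y, rcond=None)[0]
            assert fit["b1"] == pytest.approx(oracle[1], abs=1e-8)
            assert fit["b2"] == pytest.approx(oracle[2], abs=1e-8)
            assert fit["b3"] == pytest.approx(oracle[3], abs=1e-8)


class TestDeviationScan:
    def test_null_slope_near_one_intercept_near_zero(self):
        genotypes, env, y = simulate_pairs(2000, 120, {}, seed=9)
        pairs = scan_pairs(y, genotypes, env, ScanConfig(standardize_g=False))
        ranked = deviation_scan(pairs)
        assert ranked["scope_slope"].iloc[0] == pytest.approx(1.0, abs=0.05)
        assert ranked["scope_intercept"].iloc[0] == pytest.approx(0.0, abs=0.02)
        # deviations approximately t-distributed: ~5% beyond the 0.05 cut
        from scipy import stats

        crit = stats.t.ppf(0.975, df=len(ranked) - 3)
        frac = (ranked["deviation"].abs() > crit).mean()
        assert frac == pytest.approx(0.05, abs=0.04)

    def test_injected_pair_ranks_first(self):
        hits = 0
        for seed in range(10):
            genotypes, env, y = simulate_pairs(2000, 60, {7: 0.4}, seed=100 + seed)
            pairs = scan_pairs(y, genotypes, env, ScanConfig())
            ranked = deviation_scan(pairs)
            top = ranked.loc[ranked["rank"] == 1]
            if top["variant"].iloc[0] == "v00007":
                hits += 1
        assert hits >= 9

    def test_two_pairs_scope_skipped(self):
        genotypes, env, y = simulate_pairs(500, 2, {}, seed=10)
        pairs = scan_pairs(y, genotypes, env, ScanConfig())
        with pytest.warns(UserWarning, match="fewer than 3"):
            ranked = deviation_scan(pairs)
        assert ranked["skipped"].all()
        assert ranked["deviation"].isna().all()

    def test_ranks_are_permutation(self):
        genotypes, env, y = simulate_pairs(800, 30, {3: 0.5}, seed=11)
        ranked = deviation_scan(scan_pairs(y, genotypes, env))
        assert sorted(ranked["rank"].dropna()) == list(range(1, 31))

    def test_variant_order_invariance(self):
        genotypes, env, y = simulate_pairs(800, 25, {5: 0.5}, seed=12)
        ranked_fwd = deviation_scan(scan_pairs(y, genotypes, env))
        perm = np.random.default_rng(0).permutation(25)
        g_perm = genotypes.subset_variants(perm)
        ranked_perm = deviation_scan(scan_pairs(y, g_perm, env))
        a = ranked_fwd.set_index("variant")["rank"]
        b = ranked_perm.set_index("variant")["rank"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_positive_env_scaling_preserves_ranking_exactly(self):
        # E -> aE (a > 0) leaves every fitted b1 and a1 unchanged, so the
        # rank list is bit-identical
        genotypes, env, y = simulate_pairs(800, 25, {5: 0.5}, seed=13)
        ranked = deviation_scan(scan_pairs(y, genotypes, env))
        ranked2 = deviation_scan(scan_pairs(y, genotypes, env * 3.0))
        a = ranked.set_index("variant")["rank"]
        b = ranked2.set_index("variant")["rank"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_env_shift_keeps_top_pair(self):
        # a shift b changes each fitted b1 by exactly -b3_hat * b / a, so
        # null-pair ranks may permute; the interacting pair stays on top
        genotypes, env, y = simulate_pairs(800, 25, {5: 0.5}, seed=13)
        ranked = deviation_scan(scan_pairs(y, genotypes, env * 3.0 + 7.0))
        assert ranked.loc[ranked["rank"] == 1, "variant"].iloc[0] == "v00005"

    def test_power_monotone_in_beta3_and_n(self):
        # power = fraction of seeds where the injected pair ranks first
        def power(beta3, n, seeds=10):
            hits = 0
            for seed in range(seeds):
                genotypes, env, y = simulate_pairs(n, 30, {4: beta3}, seed=300 + seed)
                ranked = deviation_scan(scan_pairs(y, genotypes, env))
                if ranked.loc[ranked["rank"] == 1, "variant"].iloc[0] == "v00004":
                    hits += 1
            return hits / seeds

        grid_b = [power(b, 600) for b in (0.0, 0.1, 0.25)]
        assert grid_b[0] <= grid_b[1] <= grid_b[2]
        assert grid_b[2] > grid_b[0]
        grid_n = [power(0.12, n) for n in (150, 600, 2400)]
        assert grid_n[0] <= grid_n[1] <= grid_n[2]
        assert grid_n[2] > grid_n[0]

    def test_pooled_scope(self):
        genotypes, env, y = simulate_pairs(500, 15, {}, seed=14)
        env2 = env.copy()
        env2["env_b"] = np.random.default_rng(1).normal(size=500)
        pairs = scan_pairs(y, genotypes, env2, ScanConfig())
        ranked = deviation_scan(pairs, ScanConfig(scope="pooled"))
        assert ranked["deviation"].notna().all()
        assert sorted(ranked["rank"]) == list(range(1, 31))
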