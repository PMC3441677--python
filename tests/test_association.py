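"""Stratified regression, IVW meta-analysis, and the ancillary ancestry tests."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from admixstrat.association import (
    AllStrataDegenerateError,
    admixture_effect_test,
    allele_diff_test,
    conditional_scan,
    encode_genotype,
    hwe_exact_test,
    meta_fixed,
    ols_fit,
    stratified_assoc,
    stratum_heterogeneity_test,
)
from admixstrat.simulate import SimConfig, sample_ancestral_freqs, sample_cohort


def _cohort_fit(cohort, j, **kw):
    return stratified_assoc(
        cohort.phenotype, cohort.genotypes[:, j], cohort.local[:, j],
        cohort.age, cohort.sex, cohort.global_anc, **kw,
    )


class TestEncode:
    def test_recessive_coding(self):
        np.testing.assert_array_equal(
            encode_genotype([0, 1, 2], model="recessive"), [0.0, 0.0, 1.0]
        )

    def test_flip_maps_dosage(self):
        np.testing.assert_array_equal(encode_genotype([0, 1, 2], flip=True), [2.0, 1.0, 0.0])

    def test_additive_recessive_affine_on_homozygote_data(self):
        # with no heterozygotes, recessive = additive / 2 exactly
        d = np.array([0.0, 2.0, 2.0, 0.0, 2.0])
        np.testing.assert_array_equal(
            encode_genotype(d, model="recessive"), encode_genotype(d, model="additive") / 2
        )

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError):
            encode_genotype([0, 3, 1])


class TestOls:
    def test_exact_fit(self):
        x = np.arange(1.0, 11.0)
        res = ols_fit(2 * x, np.column_stack([np.ones(10), x]), ("const", "x"))
        assert res.beta[1] == pytest.approx(2.0, abs=1e-12)
        assert res.resid_var == pytest.approx(0.0, abs=1e-18)
        assert res.r2 == pytest.approx(1.0)

    def test_consistency_at_large_n(self, rng):
        g = rng.binomial(2, 0.3, size=10_000).astype(float)
        y = 0.5 * g + rng.normal(size=10_000)
        res = ols_fit(y, np.column_stack([np.ones_like(g), g]), ("const", "g"))
        beta, se = res["g"]
        assert abs(beta - 0.5) < 3 * se

    def test_matches_exact_rational_normal_equations(self, rng):
        # brute-force oracle: solve X'X b = X'y in exact Fraction arithmetic
        X = np.column_stack([np.ones(20), rng.integers(0, 3, 20), rng.integers(20, 60, 20)])
        y = rng.integers(-5, 15, size=20).astype(float)
        Xf = [[Fraction(int(v)) for v in row] for row in X.astype(int)]
        yf = [Fraction(int(v)) for v in y.astype(int)]
        k = 3
        xtx = [[sum(Xf[i][a] * Xf[i][b] for i in range(20)) for b in range(k)] for a in range(k)]
        xty = [sum(Xf[i][a] * yf[i] for i in range(20)) for a in range(k)]
        # gaussian elimination over Fractions
        M = [row[:] + [rhs] for row, rhs in zip(xtx, xty)]
        for col in range(k):
            piv = next(r for r in range(col, k) if M[r][col] != 0)
            M[col], M[piv] = M[piv], M[col]
            M[col] = [v / M[col][col] for v in M[col]]
            for r in range(k):
                if r != col and M[r][col] != 0:
                    M[r] = [a - M[r][col] * b for a, b in zip(M[r], M[col])]
        exact = np.array([float(M[r][k]) for r in range(k)])
        res = ols_fit(y, X, ("const", "g", "age"))
        np.testing.assert_allclose(res.beta, exact, rtol=1e-9)

    def test_singular_design_names_offending_column(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            ols_fit(rng.normal(size=30), X, ("const", "x", "dup"))


class TestMetaFixed:
    def test_single_pair_identity(self):
        beta, se, z, p = meta_fixed([0.7], [0.2])
        assert (beta, se) == (pytest.approx(0.7), pytest.approx(0.2))
        assert z == pytest.approx(3.5)

    def test_equal_se_pairs_average(self):
        beta, se, _, _ = meta_fixed([1.0, 2.0], [0.5, 0.5])
        assert beta == pytest.approx(1.5)
        assert se == pytest.approx(0.5 / np.sqrt(2))

    def test_matches_exact_weighted_mean_oracle(self):
        bs = [Fraction(1, 2), Fraction(-3, 4), Fraction(5, 8)]
        ses = [Fraction(1, 4), Fraction(1, 2), Fraction(3, 8)]
        w = [1 / s ** 2 for s in ses]
        exact_beta = sum(wi * bi for wi, bi in zip(w, bs)) / sum(w)
        beta, se, _, _ = meta_fixed([float(b) for b in bs], [float(s) for s in ses])
        assert beta == pytest.approx(float(exact_beta), rel=1e-12)
        assert se == pytest.approx(float(sum(w)) ** -0.5, rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed([], [])

    @given(
        st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.01, 3)), min_size=1, max_size=6
        ),
        st.randoms(use_true_random=False),
    )
    def test_order_invariant_and_se_bounded(self, pairs, rnd):
        betas, ses = zip(*pairs)
        a = meta_fixed(betas, ses)
        shuffled = list(pairs)
        rnd.shuffle(shuffled)
        b = meta_fixed(*zip(*shuffled))
        assert a[0] == pytest.approx(b[0], rel=1e-9, abs=1e-12)
        assert a[1] <= min(ses) + 1e-12


class TestStratifiedAssoc:
    def test_single_stratum_reduction_is_plain_ols(self, rng):
        n = 300
        g = rng.binomial(2, 0.4, n).astype(float)
        age = rng.uniform(30, 70, n)
        sex = (rng.random(n) < 0.5).astype(float)
        y = 0.3 * g + 0.01 * age + rng.normal(size=n)
        local = np.full(n, 2.0)
        theta = np.ones(n)  # constant -> dropped from the stratum design
        fit = stratified_assoc(y, g, local, age, sex, theta)
        assert [s.stratum for s in fit.strata] == [2]
        oracle = ols_fit(y, np.column_stack([np.ones(n), g, age, sex]),
                         ("const", "genotype", "age", "sex"))
        b, se = oracle["genotype"]
        assert fit.beta_meta == pytest.approx(b, rel=1e-12)
        assert fit.se_meta == pytest.approx(se, rel=1e-12)

    def test_flip_negates_beta_and_preserves_p(self, small_cohort):
        _, _, cohort, _ = small_cohort
        a = _cohort_fit(cohort, 30)
        b = _cohort_fit(cohort, 30, flip=True)
        assert b.beta_meta == pytest.approx(-a.beta_meta, rel=1e-10)
        assert b.p == pytest.approx(a.p, rel=1e-9)

    def test_planted_effect_recovered(self, small_cohort):
        _, cfg, cohort, _ = small_cohort
        fit = _cohort_fit(cohort, 30)
        assert abs(fit.beta_meta - 0.6) < 3 * fit.se_meta

    def test_small_strata_skipped_with_reason(self, rng):
        n = 60
        local = np.r_[np.full(55, 2.0), np.full(5, 0.0)]
        g = rng.binomial(2, 0.5, n).astype(float)
        fit = stratified_assoc(
            rng.normal(size=n), g, local, rng.uniform(30, 70, n),
            (rng.random(n) < 0.5).astype(float), rng.uniform(0, 1, n),
        )
        assert 0 in fit.skipped and "n=5" in fit.skipped[0]

    def test_all_strata_degenerate_raises(self, rng):
        n = 30
        g = np.zeros(n)  # monomorphic everywhere
        with pytest.raises(AllStrataDegenerateError):
            stratified_assoc(
                rng.normal(size=n), g, np.full(n, 2.0), rng.uniform(30, 70, n),
                np.zeros(n), rng.uniform(0, 1, n),
            )

    def test_agrees_with_adjusted_ols_without_confounding(self, rng):
        # fst=0: genotype independent of ancestry; stratified and pooled
        # covariate-adjusted estimates should coincide closely
        panel = sample_ancestral_freqs(10, 0.0, seed=31)
        cfg = SimConfig(n=2000, m=10, fst=0.0,
                        causal_effects={str(panel.snp_id[5]): 0.4}, seed=31)
        cohort, _ = sample_cohort(cfg, panel)
        fit = _cohort_fit(cohort, 5)
        X = np.column_stack([
            np.ones(2000), cohort.genotypes[:, 5], cohort.age, cohort.sex, cohort.global_anc,
        ])
        pooled = ols_fit(cohort.phenotype, X, ("const", "genotype", "age", "sex", "theta"))
        b, se = pooled["genotype"]
        assert fit.beta_meta == pytest.approx(b, abs=2 * se)


class TestConditionalScan:
    @staticmethod
    def _locus(rng, n=800, eps=0.05, b1=0.5, b2=0.4):
        def chrom():
            a0 = rng.random(n) < 0.5
            return np.column_stack([
                a0, a0 ^ (rng.random(n) < eps), a0 ^ (rng.random(n) < eps),
                rng.random(n) < 0.4, rng.random(n) < 0.5,
            ]).astype(float)

        G = chrom() + chrom()
        theta = rng.beta(12.0, 3.0, size=n)
        L = rng.binomial(2, theta[:, None], size=(n, 5)).astype(float)
        age, sex = rng.uniform(30, 70, n), (rng.random(n) < 0.5).astype(float)
        y = b1 * G[:, 0] + b2 * G[:, 3] + rng.normal(size=n)
        return y, G, L, age, sex, theta

    def test_self_conditioning_reported_non_testable(self, rng):
        y, G, L, age, sex, theta = self._locus(rng)
        Gdup = np.column_stack([G, G[:, 0]])  # marker 5 identical to the top SNP
        ids = [f"s{j}" for j in range(6)]
        scan = conditional_scan(y, Gdup, ids, "s0", np.column_stack([L, L[:, 0]]),
                                age, sex, theta)
        assert scan["s0"] is None
        assert scan["s5"] is None  # perfectly collinear in every stratum

    def test_secondary_recovered_and_proxies_absorbed(self, rng):
        hits_sec, prox_p = 0, []
        for _ in range(20):
            y, G, L, age, sex, theta = self._locus(rng)
            scan = conditional_scan(y, G, [f"s{j}" for j in range(5)], "s0",
                                    L, age, sex, theta)
            hits_sec += scan["s3"].p < 0.05
            prox_p += [scan["s1"].p, scan["s2"].p]
        assert hits_sec >= 18  # planted independent signal survives conditioning
        rate = np.mean(np.asarray(prox_p) < 0.05)
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(prox_p))

    def test_independent_snp_estimate_unchanged_by_conditioning(self, rng):
        y, G, L, age, sex, theta = self._locus(rng)
        plain = stratified_assoc(y, G[:, 4], L[:, 4], age, sex, theta)
        scan = conditional_scan(y, G, [f"s{j}" for j in range(5)], "s0",
                                L, age, sex, theta)
        assert scan["s4"].beta_meta == pytest.approx(plain.beta_meta, abs=0.05)


class TestHeterogeneity:
    def test_equal_effects_give_zero_z(self):
        from admixstrat.association import StratumFit, StratifiedFit

        forced = StratifiedFit(
            snp_id="x", coded_allele="A", model="additive",
            strata=[StratumFit(0, 0.5, 0.1, 50), StratumFit(2, 0.5, 0.2, 300)],
            beta_meta=0.5, se_meta=0.1, z=5.0, p=1e-6,
        )
        res = stratum_heterogeneity_test(forced)
        assert res.z == 0.0 and res.p == pytest.approx(1.0)

    def test_missing_stratum_not_testable(self):
        from admixstrat.association import StratumFit, StratifiedFit

        fit = StratifiedFit(
            snp_id="x", coded_allele="A", model="additive",
            strata=[StratumFit(2, 0.5, 0.2, 300)],
            beta_meta=0.5, se_meta=0.2, z=2.5, p=0.01,
        )
        res = stratum_heterogeneity_test(fit)
        assert not res.testable and "0" in res.reason

    def test_calibrated_under_homogeneity_and_powered_under_difference(self, rng):
        rej_null = rej_diff = 0
        reps = 60
        for _ in range(reps):
            n = 900
            local = rng.integers(0, 3, n).astype(float)
            g = rng.binomial(2, 0.5, n).astype(float)
            age = rng.uniform(30, 70, n)
            sex = (rng.random(n) < 0.5).astype(float)
            theta = rng.uniform(0.4, 1.0, n)
            y0 = 0.3 * g + rng.normal(size=n)
            beta_by_stratum = np.where(local == 0, 0.0, np.where(local == 2, 1.0, 0.5))
            y1 = beta_by_stratum * g + rng.normal(size=n)
            for y, counter in ((y0, "null"), (y1, "diff")):
                fit = stratified_assoc(y, g, local, age, sex, theta)
                res = stratum_heterogeneity_test(fit)
                if res.testable and res.p < 0.05:
                    if counter == "null":
                        rej_null += 1
                    else:
                        rej_diff += 1
        assert rej_null / reps < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
        assert rej_diff / reps > 0.8


class TestAdmixtureEffect:
    def test_recovers_planted_ancestry_effect(self):
        panel = sample_ancestral_freqs(30, 0.2, seed=32)
        cfg = SimConfig(n=2000, m=30, fst=0.2, ancestry_effect=1.0,
                        ancestry_marker=str(panel.snp_id[15]), seed=32)
        cohort, _ = sample_cohort(cfg, panel)
        beta, se, p = admixture_effect_test(
            cohort.phenotype, cohort.local[:, 15], cohort.age, cohort.sex, cohort.global_anc
        )
        assert abs(beta - 1.0) < 3 * se
        assert p < 0.01

    def test_calibrated_under_null(self, rng):
        rej, reps = 0, 150
        for _ in range(reps):
            seed = int(rng.integers(2 ** 31))
            panel = sample_ancestral_freqs(20, 0.2, seed=seed)
            cohort, _ = sample_cohort(SimConfig(n=400, m=20, fst=0.2, seed=seed), panel)
            _, _, p = admixture_effect_test(
                cohort.phenotype, cohort.local[:, 10], cohort.age, cohort.sex, cohort.global_anc
            )
            rej += p < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.05)

    def test_constant_local_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            admixture_effect_test(
                rng.normal(size=50), np.full(50, 2.0), rng.uniform(30, 70, 50),
                np.zeros(50), rng.uniform(0, 1, 50),
            )


class TestAlleleDiff:
    def test_identical_proportions(self):
        chi2, p = allele_diff_test(30, 100, 30, 100)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_2x2_closed_form(self):
        # table [[30,70],[70,30]]: chi2 = n(ad-bc)^2 / (row/col products) = 32
        chi2, p = allele_diff_test(30, 100, 70, 100)
        a, b, c, d = 30, 70, 70, 30
        n = a + b + c + d
        exact = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(exact, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(exact, 1), rel=1e-12)

    def test_matches_statsmodels_proportions_chisquare(self):
        from statsmodels.stats.proportion import proportions_chisquare

        chi2, p = allele_diff_test(17, 60, 33, 82)
        sm_chi2, sm_p, _ = proportions_chisquare([17, 33], [60, 82])
        assert chi2 == pytest.approx(sm_chi2, rel=1e-10)
        assert p == pytest.approx(sm_p, rel=1e-10)

    def test_calibrated_at_zero_fst(self, rng):
        panel = sample_ancestral_freqs(4000, 0.0, seed=33)
        _, p = allele_diff_test(
            panel.count_afr, panel.n_chrom_afr, panel.count_eur, panel.n_chrom_eur
        )
        rate = np.mean(p < 0.05)
        assert rate == pytest.approx(0.05, abs=0.015)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            allele_diff_test(0, 0, 5, 10)


class TestHweExact:
    def test_perfect_equilibrium_large_p(self):
        p, flag = hwe_exact_test(25, 50, 25)
        assert p == pytest.approx(1.0)

    def test_extreme_heterozygote_excess(self):
        p, flag = hwe_exact_test(0, 100, 0)
        assert p < 1e-20 and flag

    def test_matches_exact_rational_enumeration(self, rng):
        from math import comb

        for _ in range(60):
            n = int(rng.integers(2, 40))
            n_A = int(rng.integers(0, 2 * n + 1))
            parity = n_A % 2
            hs = range(parity, min(n_A, 2 * n - n_A) + 1, 2)
            if not list(hs):
                continue
            # exact conditional pmf: multinomial count * 2^h / C(2n, nA)
            weights = {
                h: comb(n, (n_A - h) // 2) * comb(n - (n_A - h) // 2, h) * 2 ** h
                for h in hs
            }
            total = sum(weights.values())
            h_obs = int(rng.choice(list(weights)))
            p_obs = weights[h_obs]
            exact_p = sum(w for w in weights.values() if w <= p_obs) / total
            got_p, got_flag = hwe_exact_test((n_A - h_obs) // 2, h_obs,
                                             (2 * n - n_A - h_obs) // 2)
            assert got_p == pytest.approx(exact_p, rel=1e-9)
            exact_e_het = sum(h * w for h, w in weights.items()) / total
            assert got_flag == (h_obs > exact_e_het)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)
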