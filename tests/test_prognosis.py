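"""Statistical layer: rank-sum, BH, Kaplan-Meier/log-rank, Cox, Spearman."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from folliscape.prognosis import (
    bh_adjust,
    compare_groups,
    cox_multivariate,
    encode_flipi,
    median_split_km,
    run_association_suite,
    spearman_assoc,
)
from folliscape.synthetic_data import CohortConfig, SceneConfig, generate_cohort


class TestRankSum:
    def test_identical_groups_p_is_one(self):
        r = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert r.p_raw == 1.0
        assert r.method == "exact"

    def test_fully_separated_small_groups(self):
        r = compare_groups({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert r.p_raw == pytest.approx(0.1)
        assert r.statistic == 0.0

    def test_asymptotic_close_to_permutation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            a = rng.normal(0, 1, 15)
            b = rng.normal(0.6, 1, 15)
            r = compare_groups({"a": a, "b": b})
            assert r.method == "asymptotic"
            # permutation oracle
            combined = np.concatenate([a, b])
            ranks = stats.rankdata(combined)
            u_obs = ranks[:15].sum() - 15 * 16 / 2
            dev = abs(u_obs - 15 * 15 / 2)
            hits = 0
            n_perm = 20000
            prng = np.random.default_rng(1)
            for _ in range(n_perm):
                perm = prng.permutation(ranks)
                u = perm[:15].sum() - 15 * 16 / 2
                hits += abs(u - 112.5) >= dev - 1e-9
            assert r.p_raw == pytest.approx(hits / n_perm, abs=0.02)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            compare_groups({"a": [np.nan], "b": [1.0, 2.0]}, feature="dens")


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_stepup_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    def test_order_invariance_and_monotonicity(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.001, 1.0, 12)
        adj = bh_adjust(p)
        perm = rng.permutation(12)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])
        # ranking preserved
        assert (np.argsort(np.argsort(p)) == np.argsort(np.argsort(adj, kind="stable"))).all() or (
            np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)
        )

    def test_matches_stepup_definition_on_small_inputs(self):
        # independent implementation of the step-up rule with cumulative min
        rng = np.random.default_rng(6)
        for _ in range(20):
            m = rng.integers(1, 9)
            p = rng.uniform(0.001, 1.0, m)
            order = np.argsort(p)
            raw = p[order] * m / (np.arange(m) + 1)
            adj_sorted = np.minimum.accumulate(raw[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(adj_sorted, 1.0)
            np.testing.assert_allclose(bh_adjust(p), expected)


class TestSurvival:
    def test_cloned_arms_give_null_logrank(self):
        t = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        v = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)  # split reproduces clones
        r = median_split_km(v, t, e)
        assert r.statistic == pytest.approx(0.0, abs=1e-9)
        assert r.p == pytest.approx(1.0)

    def test_km_product_limit_identities(self):
        # events at 1,2,3 in the low arm, no censoring: S = 2/3, 1/3, 0
        v = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        t = np.array([1, 2, 3, 10, 20, 30], dtype=float)
        e = np.ones(6, dtype=int)
        r = median_split_km(v, t, e)
        km = r.km_low.set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(2 / 3)
        assert km.loc[2.0] == pytest.approx(1 / 3)
        assert km.loc[3.0] == pytest.approx(0.0)

    def test_logrank_matches_exhaustive_permutation(self):
        # arms {1,2,3} vs {10,20,30}, all events: exhaustive label permutation
        from lifelines.statistics import logrank_test

        t = np.array([1, 2, 3, 10, 20, 30], dtype=float)
        e = np.ones(6, dtype=int)
        obs = logrank_test(t[:3], t[3:], e[:3], e[3:]).test_statistic
        stats_all = []
        for idx in itertools.combinations(range(6), 3):
            arm = np.zeros(6, dtype=bool)
            arm[list(idx)] = True
            stats_all.append(logrank_test(t[arm], t[~arm], e[arm], e[~arm]).test_statistic)
        perm_p = np.mean([s >= obs - 1e-9 for s in stats_all])
        r = median_split_km(np.array([0, 0, 0, 1, 1, 1], float), t, e)
        # chi2 p of the observed statistic should be of the same order as
        # the exact permutation p (small-sample discreteness allowed)
        assert r.statistic == pytest.approx(obs)
        assert perm_p == pytest.approx(0.1, abs=1e-9)
        assert r.p < 0.05  # asymptotic p for maximal separation

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="median split"):
            median_split_km([1.0] * 6, np.arange(1, 7, dtype=float), np.ones(6, int))


class TestCox:
    def test_rescaling_covariate_rescales_coefficient(self):
        rng = np.random.default_rng(7)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.2 * np.exp(0.8 * x)))
        e = (t < 10).astype(int)
        t = np.minimum(t, 10)
        f1 = cox_multivariate(pd.DataFrame({"x": x}), t, e)
        f2 = cox_multivariate(pd.DataFrame({"x": x * 10}), t, e)
        assert f2.table["coef"].iloc[0] == pytest.approx(f1.table["coef"].iloc[0] / 10, rel=1e-4)
        assert f2.table["p"].iloc[0] == pytest.approx(f1.table["p"].iloc[0], abs=1e-6)

    def test_two_group_hr_matches_exponential_rate_ratio(self):
        rng = np.random.default_rng(8)
        n = 500
        g = (rng.random(n) < 0.5).astype(float)
        rate = np.where(g == 1, 0.6, 0.2)
        t = rng.exponential(1.0 / rate)
        e = np.ones(n, dtype=int)
        fit = cox_multivariate(pd.DataFrame({"g": g}), t, e)
        # closed-form MLE of the rate ratio for exponential samples
        ratio = (e[g == 1].sum() / t[g == 1].sum()) / (e[g == 0].sum() / t[g == 0].sum())
        assert fit.table["hr"].iloc[0] == pytest.approx(ratio, rel=0.1)

    def test_ci_contains_hr_and_hr_positive(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=80)
        t = rng.exponential(2.0, 80)
        e = np.ones(80, dtype=int)
        fit = cox_multivariate(pd.DataFrame({"x": x}), t, e)
        row = fit.table.iloc[0]
        assert row["ci_low"] <= row["hr"] <= row["ci_high"]
        assert row["hr"] > 0

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_multivariate(pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [0.0, 1.0, 0.0],
                                           "z": [1.0, 0.0, 1.0]}),
                             [1.0, 2.0, 3.0], [1, 0, 0])

    def test_flipi_encodings(self):
        s = ["low", "high", "intermediate", "low"]
        ordinal = encode_flipi(s)
        np.testing.assert_array_equal(ordinal["flipi"], [0, 2, 1, 0])
        onehot = encode_flipi(s, one_hot=True)
        assert list(onehot.columns) == ["flipi_intermediate", "flipi_high"]
        with pytest.raises(ValueError, match="FLIPI"):
            encode_flipi(["low", "unknown"])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_assoc(np.arange(10.0), np.arange(10.0))[0] == pytest.approx(1.0)
        assert spearman_assoc(np.arange(10.0), -np.arange(10.0))[0] == pytest.approx(-1.0)

    def test_constant_input_missing(self):
        r, p = spearman_assoc(np.ones(8), np.arange(8.0))
        assert np.isnan(r) and np.isnan(p)

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rho, p = spearman_assoc(x, y)
        # independent oracle: scipy statistic over all 8! rank pairings
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(stats.spearmanr(rx, ry).statistic)
        hits = total = 0
        for perm in itertools.permutations(range(8)):
            r = stats.spearmanr(rx, ry[list(perm)]).statistic
            hits += abs(r) >= obs - 1e-12
            total += 1
        assert p == pytest.approx(hits / total)


@pytest.fixture(scope="module")
def cohort_table():
    scene = SceneConfig(width_um=200, height_um=200, n_follicles=0,
                        phenotype_densities={"CD8+FOXP3+": (0.3, 1.0), "CD4+CD8+": (0.3, 1.0)},
                        coupling={("CD8+FOXP3+", "CD4+CD8+"): (0.5, 8.0)})
    cfg = CohortConfig(n_patients=40, tiles_per_patient=1, scene=scene,
                       hazard_spec={"coloc_CD8+FOXP3+__CD4+CD8+": -1.0}, seed=3)
    _, clin = generate_cohort(cfg, scenes=False)
    return clin.rename(columns={
        "true_density_CD8+FOXP3+_inter": "density_CD8+FOXP3+_inter",
        "true_density_CD8+FOXP3+_intra": "density_CD8+FOXP3+_intra",
        "true_coloc_CD8+FOXP3+__CD4+CD8+": "coloc_CD8+FOXP3+__CD4+CD8+_inter",
    })


class TestAssociationSuite:

    def test_row_bookkeeping_and_bh_families(self, cohort_table):
        feats = ["density_CD8+FOXP3+_inter", "density_CD8+FOXP3+_intra",
                 "coloc_CD8+FOXP3+__CD4+CD8+_inter"]
        out = run_association_suite(cohort_table, feats)
        assert len(out) == len(feats)
        assert set(out["family"]) == {"density", "coloc"}
        assert (out["p_bh"] >= out["p_raw"] - 1e-12).all()

    def test_joint_cox_model_reported_for_headline_pair(self, cohort_table):
        feats = ["density_CD8+FOXP3+_inter", "coloc_CD8+FOXP3+__CD4+CD8+_inter"]
        out = run_association_suite(cohort_table, feats, headline_pair=tuple(feats))
        assert out["joint_cox_p"].notna().sum() == 2

    def test_high_missingness_feature_dropped_with_warning(self, cohort_table):
        t = cohort_table.copy()
        t["density_CD8+FOXP3+_inter"] = np.nan
        with pytest.warns(UserWarning, match="dropped"):
            out = run_association_suite(
                t, ["density_CD8+FOXP3+_inter", "coloc_CD8+FOXP3+__CD4+CD8+_inter"])
        assert len(out) == 1

    def test_too_small_cohort_rejected(self, cohort_table):
        with pytest.raises(ValueError, match="at least 10"):
            run_association_suite(cohort_table.head(5), ["density_CD8+FOXP3+_inter"])
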