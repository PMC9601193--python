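"""OPLS-DA fitting, VIP scores, outlier diagnostics and permutation validation."""

import numpy as np
import pytest

from effluxsig.opls import (
    cross_validated_q2,
    fit_opls_da,
    outlier_report,
    permutation_test,
    remove_outliers_and_refit,
    select_n_orthogonal,
    vip_scores,
)
from effluxsig.peaks import total_sum_normalize
from effluxsig.simulate import Scenario, builtin_scenarios, generate_peak_table

from conftest import make_table


def labels_of(table):
    return table.binary_labels()


class TestFit:
    def test_matches_one_component_pls_when_no_orthogonal(self, two_class_table):
        from sklearn.cross_decomposition import PLSRegression

        y = labels_of(two_class_table)
        x = two_class_table.areas.to_numpy()
        model = fit_opls_da(two_class_table, y, n_orthogonal=0)
        pls = PLSRegression(n_components=1, scale=True).fit(x, y.astype(float))
        assert np.max(np.abs(model.predict(x) - pls.predict(x).ravel())) <= 1e-8

    def test_orthogonal_scores_orthogonal_to_predictive(self, two_class_table):
        y = labels_of(two_class_table)
        m = fit_opls_da(two_class_table, y, n_orthogonal=2)
        t = m.scores
        for a in range(m.n_orthogonal):
            t_o = m.ortho_scores[:, a]
            assert abs(t @ t_o) <= 1e-8 * np.linalg.norm(t) * np.linalg.norm(t_o)

    def test_variance_fractions_in_range(self, two_class_table):
        m = fit_opls_da(two_class_table, labels_of(two_class_table), n_orthogonal=1)
        assert 0 <= m.r2x <= 1
        assert 0 <= m.r2y <= 1

    def test_loading_concentrates_on_separating_variable(self):
        # class means differ on variable 1 only
        rng = np.random.default_rng(0)
        x = rng.lognormal(mean=5.0, sigma=0.05, size=(12, 2))
        x[:6, 0] *= 4.0
        t = make_table(x)
        m = fit_opls_da(t, labels_of(t), n_orthogonal=0)
        w = np.abs(m.weights)
        assert w[0] ** 2 > 0.9  # >90% of the squared predictive weight

    def test_single_class_labels_error(self, two_class_table):
        with pytest.raises(ValueError, match="two classes"):
            fit_opls_da(two_class_table, np.ones(12))

    def test_rank_exhaustion_error(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(sigma=0.2, size=(6, 3))
        t = make_table(x, groups=["treated"] * 3 + ["control"] * 3)
        with pytest.raises(ValueError, match="rank|covariance"):
            fit_opls_da(t, labels_of(t), n_orthogonal=5)

    def test_null_labels_give_low_q2(self, null_table):
        # median cross-validated q2 over random relabelings stays below 0.2
        rng = np.random.default_rng(0)
        q2s = []
        for _ in range(20):
            y = rng.permutation([1] * 6 + [0] * 6)
            q2s.append(cross_validated_q2(null_table, y, n_orthogonal=0, seed=1))
        assert np.median(q2s) < 0.2


class TestComponentSelection:
    def test_max_k_zero(self, two_class_table):
        assert select_n_orthogonal(two_class_table, labels_of(two_class_table), max_k=0) == 0

    def test_no_orthogonal_structure_selects_zero(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(mean=4.0, sigma=0.05, size=(12, 6))
        x[:6] *= 2.0  # pure class shift on every variable, no confounder
        t = make_table(x)
        assert select_n_orthogonal(t, labels_of(t), max_k=2) == 0

    def test_strong_confounder_selects_one(self):
        # y-orthogonal confounder direction dominates X variance
        rng = np.random.default_rng(2)
        n, p = 24, 12
        y = np.array([1] * 12 + [0] * 12)
        confounder = np.tile([1.0, -1.0], n // 2)  # orthogonal to y by design
        x = np.exp(
            0.03 * rng.standard_normal((n, p))
            + 0.4 * np.outer(y - y.mean(), np.r_[np.ones(4), np.zeros(p - 4)])
            + 1.5 * np.outer(confounder, np.r_[np.zeros(4), np.ones(p - 4)])
        )
        t = make_table(x, groups=["treated"] * 12 + ["control"] * 12)
        assert select_n_orthogonal(t, y, max_k=2) == 1

    def test_too_many_folds_error(self, two_class_table):
        with pytest.raises(ValueError, match="exceeds"):
            cross_validated_q2(two_class_table, labels_of(two_class_table), cv_folds=13)


class TestVip:
    def test_mean_square_is_one_on_any_fit(self, two_class_table, null_table):
        for table in (two_class_table, null_table):
            y = labels_of(table)
            for k in (0, 1):
                m = fit_opls_da(table, y, n_orthogonal=k)
                v = vip_scores(m, table, y)
                assert np.mean(v.vip**2) == pytest.approx(1.0, abs=1e-8)

    def test_exchangeable_variables_all_one(self):
        # identical informativeness: duplicate the same variable three times
        rng = np.random.default_rng(3)
        col = rng.lognormal(sigma=0.1, size=12)
        col[:6] *= 2
        noise = 1 + 1e-6 * rng.standard_normal((12, 3))
        t = make_table(np.column_stack([col, col, col]) * noise)
        m = fit_opls_da(t, labels_of(t), n_orthogonal=0)
        v = vip_scores(m, t, labels_of(t))
        assert np.allclose(v.vip, 1.0, atol=1e-3)

    def test_matches_hand_computed_formula(self):
        # 3-variable toy: VIP_j = sqrt(p) |w_j| / ||w|| for one component
        rng = np.random.default_rng(4)
        x = rng.lognormal(sigma=0.3, size=(10, 3))
        x[:5, 1] *= 3
        t = make_table(x, groups=["treated"] * 5 + ["control"] * 5)
        y = labels_of(t)
        m = fit_opls_da(t, y, n_orthogonal=0)
        v = vip_scores(m, t, y)
        expected = np.sqrt(3) * np.abs(m.weights) / np.linalg.norm(m.weights)
        assert np.allclose(v.vip, expected, atol=1e-12)

    def test_dimension_mismatch(self, two_class_table, null_table):
        y = labels_of(two_class_table)
        m = fit_opls_da(two_class_table, y)
        with pytest.raises(ValueError):
            vip_scores(m, null_table, labels_of(null_table))


class TestOutliers:
    def _clean_table(self, seed=0):
        scen = Scenario(name="clean", transporter="pgp", role="inhibitor",
                        effects={"pantothenate": 1.6}, noise_cv=0.05, outlier_rate=0.0)
        table, _ = generate_peak_table(scen, n_metabolites=30, seed=seed)
        return total_sum_normalize(table, control_analyte="olomoucine")

    def test_duplicated_sample_not_flagged(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(sigma=0.2, size=(11, 8))
        x = np.vstack([x, x[0]])  # exact duplicate of sample 1
        t = make_table(x)
        y = labels_of(t)
        m = fit_opls_da(t, y, n_orthogonal=0)
        rep = outlier_report(m, t)
        assert "s12" not in rep.flagged_ids and "s1" not in rep.flagged_ids

    def test_distorted_sample_flagged(self):
        t = self._clean_table()
        rng = np.random.default_rng(9)
        areas = t.areas.copy()
        areas.iloc[2] *= rng.lognormal(sigma=np.log(5), size=areas.shape[1])
        areas.iloc[2] /= areas.iloc[2].sum()
        bad = type(t)(areas=areas, groups=t.groups, normalized=True)
        y = labels_of(bad)
        m = fit_opls_da(bad, y, n_orthogonal=0)
        rep = outlier_report(m, bad)
        assert bad.sample_ids[2] in rep.flagged_ids

    def test_critical_values_monotone_in_alpha(self, two_class_table):
        y = labels_of(two_class_table)
        m = fit_opls_da(two_class_table, y)
        r05 = outlier_report(m, two_class_table, alpha=0.05)
        r10 = outlier_report(m, two_class_table, alpha=0.10)
        assert r05.dmodx_critical > r10.dmodx_critical
        assert r05.t2_critical > r10.t2_critical

    def test_alpha_range_enforced(self, two_class_table):
        m = fit_opls_da(two_class_table, labels_of(two_class_table))
        with pytest.raises(ValueError):
            outlier_report(m, two_class_table, alpha=1.5)

    def test_clean_data_removes_nothing(self):
        t = self._clean_table()
        y = labels_of(t)
        kept, _, rep = remove_outliers_and_refit(t, y)
        assert kept.n_samples == t.n_samples

    def test_max_rounds_limits_passes(self, null_table):
        t = total_sum_normalize(null_table)
        y = labels_of(t)
        kept1, _, _ = remove_outliers_and_refit(t, y, max_rounds=1)
        # one pass removes at most the first round's flags
        m = fit_opls_da(t, y)
        first_flags = set(outlier_report(m, t).flagged_ids)
        removed = set(t.sample_ids) - set(kept1.sample_ids)
        assert removed <= first_flags

    def test_removed_subset_of_planted_outliers(self):
        scen = Scenario(name="o", transporter="pgp", role="inhibitor",
                        effects={"pantothenate": 1.6}, noise_cv=0.05,
                        outlier_rate=0.1, n_treated=6, n_control=6)
        ok = 0
        for seed in range(50):
            table, truth = generate_peak_table(scen, n_metabolites=30, seed=seed)
            norm = total_sum_normalize(table, control_analyte="olomoucine")
            y = norm.binary_labels()
            try:
                kept, _, _ = remove_outliers_and_refit(norm, y)
            except ValueError:
                continue
            removed = set(norm.sample_ids) - set(kept.sample_ids)
            ok += removed <= set(truth.outlier_samples)
        assert ok >= 45  # >=90% of 50 seeds


class TestPermutation:
    def _separated(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(sigma=0.05, size=(12, 10))
        x[:6, :5] *= 3.0
        return make_table(x)

    def test_strong_effect_minimal_p(self):
        t = self._separated()
        y = labels_of(t)
        res = permutation_test(t, y, n_permutations=99, seed=0)
        assert res.p_value_q2 == pytest.approx(1 / 100)
        assert res.observed_q2 > max(res.permuted_q2)

    def test_addone_formula_at_19_permutations(self):
        t = self._separated()
        res = permutation_test(t, labels_of(t), n_permutations=19, seed=0)
        assert np.all(res.permuted_q2 < res.observed_q2)
        assert res.p_value_q2 == pytest.approx(0.05)

    def test_deterministic_given_seed(self, null_table):
        y = labels_of(null_table)
        a = permutation_test(null_table, y, n_permutations=19, seed=5)
        b = permutation_test(null_table, y, n_permutations=19, seed=5)
        assert np.array_equal(a.permuted_q2, b.permuted_q2)

    def test_minimum_permutations_enforced(self, null_table):
        with pytest.raises(ValueError):
            permutation_test(null_table, labels_of(null_table), n_permutations=5)
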