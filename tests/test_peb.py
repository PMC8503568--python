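import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from spdcm.cohort import ParticipantRecord
from spdcm.peb import (
    DesignError,
    PebDesign,
    bayesian_model_reduction,
    bma_search,
    build_design,
    build_within_group_age_design,
    decision_rule,
    fit_peb,
)


def _records(n=40, n_sites=4, seed=0, equal_ages=False):
    rng = np.random.default_rng(seed)
    recs = []
    sites = rng.integers(0, n_sites, size=n)
    sites[:n_sites] = np.arange(n_sites)  # every site populated
    for i in range(n):
        group = "ASD" if i % 2 == 0 else "TD"
        age = 20.0 if equal_ages else float(rng.uniform(8, 40))
        recs.append(
            ParticipantRecord(
                subject_id=f"s{i:03d}",
                group=group,
                age=age,
                mean_fd=float(rng.uniform(0.05, 0.3)),
                site=f"site{sites[i]}",
                srs_total=float(rng.uniform(5, 150)),
            )
        )
    return recs


class TestBuildDesign:
    def test_eight_sites_give_seven_dummies(self):
        recs = _records(n=80, n_sites=8)
        design = build_design(recs, site_mode="dummies")
        assert design.n_covariates == 5 + 7
        assert sum(c.startswith("site_") for c in design.column_labels) == 7

    def test_column_order_and_centering(self):
        design = build_design(_records(), site_mode="none")
        assert design.column_labels[:5] == ("mean", "age", "group", "age_x_group", "FD")
        x = design.matrix
        np.testing.assert_allclose(x[:, 1:].mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(x[:, 1].std(), 1.0)  # age z-scored

    def test_orthogonalized_dummies_are_orthogonal(self):
        recs = _records(n=120, n_sites=8, seed=3)
        design = build_design(recs, site_mode="orthogonalized")
        x = design.matrix
        age = x[:, 1]
        inter = x[:, 3]
        sites = x[:, 5:]
        assert np.abs(sites.T @ age).max() < 1e-10
        assert np.abs(sites.T @ inter).max() < 1e-10
        gram = sites.T @ sites
        assert np.abs(gram - np.diag(np.diag(gram))).max() < 1e-10

    def test_orthogonalization_preserves_column_span(self):
        # projection matrices equal => identical fitted values, only the
        # attribution of shared variance moves
        recs = _records(n=100, n_sites=6, seed=4)
        p = {}
        for mode in ("dummies", "orthogonalized"):
            x = build_design(recs, site_mode=mode).matrix
            p[mode] = x @ np.linalg.pinv(x)
        assert np.abs(p["dummies"] - p["orthogonalized"]).max() < 1e-10

    def test_degenerate_equal_ages_is_rank_error(self):
        with pytest.raises(DesignError):
            build_design(_records(n=6, equal_ages=True), site_mode="none")

    def test_single_site_with_dummies_rejected(self):
        recs = _records(n=10, n_sites=1)
        with pytest.raises(DesignError, match="site"):
            build_design(recs, site_mode="dummies")


class TestWithinGroupDesign:
    def test_columns_and_indicator_structure(self):
        recs = _records(n=30)
        design = build_within_group_age_design(recs)
        assert design.column_labels == ("mean", "group", "age_TD", "age_ASD", "FD")
        td = np.array([r.group == "TD" for r in recs])
        x = design.matrix
        assert np.all(x[~td, 2] == 0.0)  # ASD subjects have no age_TD entry
        assert np.all(x[td, 3] == 0.0)

    def test_age_columns_partition_groupwise_centered_age(self):
        recs = _records(n=30)
        design = build_within_group_age_design(recs)
        x = design.matrix
        combined = x[:, 2] + x[:, 3]
        age = np.array([r.age for r in recs])
        gvec = np.array([r.group for r in recs])
        centered = age.copy()
        for g in ("ASD", "TD"):
            centered[gvec == g] -= age[gvec == g].mean()
        centered /= centered.std(ddof=0)
        np.testing.assert_allclose(combined, centered, atol=1e-12)


def _toy_posteriors(n, k, beta, x, noise_sd, rng, post_var=1e-4):
    posts = []
    for i in range(n):
        theta = x[i] @ beta.T + rng.normal(0, noise_sd, k)
        posts.append((theta, post_var * np.eye(k)))
    return posts


class TestFitPeb:
    def test_identical_subjects_shrink_toward_zero_vanishing_with_n(self):
        m = np.array([0.4, -0.2])
        c = 0.01 * np.eye(2)
        est = {}
        for n in (4, 64):
            design = PebDesign(np.ones((n, 1)), ("mean",))
            peb = fit_peb([(m, c)] * n, design)
            est[n] = peb.beta_mean[:, 0]
            # shrinkage: between 0 and m, same sign
            assert np.all(np.abs(est[n]) <= np.abs(m))
            assert np.all(np.sign(est[n]) == np.sign(m))
        assert np.all(np.abs(est[64] - m) < np.abs(est[4] - m) + 1e-12)

    def test_tight_first_level_recovers_ols(self, rng):
        n, k, p = 60, 3, 2
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = np.array([[0.3, 0.1], [-0.2, 0.05], [0.0, -0.1]])  # (K, P)
        posts = _toy_posteriors(n, k, beta, x, 0.0, rng, post_var=1e-8)
        design = PebDesign(x, ("mean", "age"))
        peb = fit_peb(posts, design)
        np.testing.assert_allclose(peb.beta_mean, beta, atol=1e-3)

    def test_subject_permutation_invariance(self, rng):
        n, k = 20, 2
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = np.array([[0.2, 0.1], [0.0, -0.2]])
        posts = _toy_posteriors(n, k, beta, x, 0.05, rng)
        design = PebDesign(x, ("mean", "age"))
        peb1 = fit_peb(posts, design)
        perm = rng.permutation(n)
        design2 = PebDesign(x[perm], ("mean", "age"))
        peb2 = fit_peb([posts[i] for i in perm], design2)
        np.testing.assert_allclose(peb1.beta_mean, peb2.beta_mean, atol=1e-8)

    def test_row_mismatch_rejected(self, rng):
        design = PebDesign(np.ones((3, 1)), ("mean",))
        posts = _toy_posteriors(2, 1, np.zeros((1, 1)), np.ones((2, 1)), 0.1, rng)
        with pytest.raises(ValueError, match="posteriors"):
            fit_peb(posts, design)


class TestBayesianModelReduction:
    def test_identity_reduction_changes_nothing(self, rng):
        m0, c0 = np.zeros(3), np.eye(3)
        m = rng.normal(0, 0.5, 3)
        a = rng.standard_normal((3, 3))
        c = 0.1 * (a @ a.T + 3 * np.eye(3))
        mr, cr, df = bayesian_model_reduction(m0, c0, m, c, m0, c0)
        np.testing.assert_allclose(mr, m, atol=1e-12)
        np.testing.assert_allclose(cr, c, atol=1e-12)
        assert df == pytest.approx(0.0, abs=1e-12)

    def test_one_dimensional_matches_conjugate_refit(self):
        # likelihood implied by (prior, posterior); refit under reduced prior
        # done independently with scalar conjugate-Gaussian algebra
        v0, vp = 1.0, 0.5
        m0, mp = 0.0, 0.5
        v0r, m0r = 1e-8, 0.0
        # implied likelihood: precision and natural mean
        pl = 1 / vp - 1 / v0
        hl = mp / vp - m0 / v0
        pr = pl + 1 / v0r
        mr_expect = (hl + m0r / v0r) / pr
        mr, cr, df = bayesian_model_reduction(
            [m0], [[v0]], [mp], [[vp]], [m0r], [[v0r]]
        )
        assert mr[0] == pytest.approx(mr_expect, abs=1e-6)
        assert cr[0, 0] == pytest.approx(1 / pr, rel=1e-6)
        # evidence ratio by direct numerical integration of the implied
        # likelihood against both priors
        lik = lambda t: np.exp(-0.5 * pl * t**2 + hl * t)
        z_full = quad(lambda t: lik(t) * norm.pdf(t, m0, np.sqrt(v0)), -10, 10)[0]
        z_red = quad(
            lambda t: lik(t) * norm.pdf(t, m0r, np.sqrt(v0r)), -1e-3, 1e-3,
            points=[0.0],
        )[0]
        assert df == pytest.approx(np.log(z_red / z_full), abs=1e-4)

    def test_independent_parameter_untouched_by_pruning(self):
        m0 = np.zeros(2)
        c0 = np.diag([1.0, 1.0])
        m = np.array([0.3, -0.4])
        c = np.diag([0.2, 0.3])
        mr, cr, _ = bayesian_model_reduction(
            m0, c0, m, c, np.zeros(2), np.diag([1.0, 1e-8])
        )
        assert mr[0] == pytest.approx(m[0], abs=1e-8)
        assert cr[0, 0] == pytest.approx(c[0, 0], rel=1e-8)
        assert abs(mr[1]) < 1e-6

    def test_invalid_reduction_reports_minus_inf(self):
        # reduced prior wider than the posterior supports can break PD-ness
        m0, c0 = np.zeros(1), np.array([[1e-8]])
        m, c = np.array([0.1]), np.array([[0.5]])
        _, _, df = bayesian_model_reduction(m0, c0, m, c, np.zeros(1), np.array([[10.0]]))
        assert df == -np.inf


class TestBmaSearch:
    def _small_peb(self, beta_true, noise_sd, rng, n=80):
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        k = beta_true.shape[0]
        posts = _toy_posteriors(n, k, beta_true, x, noise_sd, rng)
        design = PebDesign(x, ("mean", "age"))
        return fit_peb(posts, design)

    def test_greedy_agrees_with_exhaustive(self, rng):
        peb = self._small_peb(np.array([[0.3, 0.15], [0.0, 0.0]]), 0.05, rng)
        greedy = bma_search(peb, search="greedy")
        exhaustive = bma_search(peb, search="exhaustive")
        np.testing.assert_allclose(
            greedy.posterior_prob, exhaustive.posterior_prob, atol=0.02
        )

    def test_null_effect_not_flagged(self, rng):
        peb = self._small_peb(np.array([[0.3, 0.0]]), 0.02, rng)
        bma = bma_search(peb, search="exhaustive")
        p_age = bma.posterior_prob[0, 1]
        assert p_age < 0.5
        assert bma.ci90_low[0, 1] <= 0 <= bma.ci90_high[0, 1]
        assert not bma.significant[0, 1]

    def test_true_effect_flagged_with_consistent_ci(self, rng):
        peb = self._small_peb(np.array([[0.3, 0.2]]), 0.02, rng)
        bma = bma_search(peb, search="exhaustive")
        assert bma.significant[0, 1]
        assert bma.ci90_low[0, 1] > 0
        assert bma.posterior_prob[0, 1] > 0.90

    def test_report_rows_internally_consistent(self, rng):
        # significant <=> CI excludes zero <=> posterior prob > 0.90, on
        # every report row by construction
        peb = self._small_peb(np.array([[0.25, 0.1], [0.0, -0.15]]), 0.05, rng)
        df = bma_search(peb, search="exhaustive").to_frame()
        for _, row in df.iterrows():
            ci_excl = row.ci_low > 0 or row.ci_high < 0
            assert row.significant == ci_excl == (row.posterior_prob > 0.90)

    def test_averaged_mean_in_convex_hull_of_member_models(self, rng):
        # independent enumeration of the model space using the BMR primitive
        from itertools import product as iproduct
        from spdcm.peb import OFF_PRIOR_VAR

        peb = self._small_peb(np.array([[0.2, 0.1]]), 0.05, rng)
        bma = bma_search(peb, search="exhaustive")
        kp = peb.beta_cov.shape[0]
        vec_mean = peb.beta_mean.T.reshape(-1)
        means, log_evs = [], []
        for bits in iproduct([False, True], repeat=kp):
            var = peb.prior_var.copy()
            var[np.asarray(bits)] = OFF_PRIOR_VAR
            mr, _, df = bayesian_model_reduction(
                peb.prior_mean, np.diag(peb.prior_var), vec_mean, peb.beta_cov,
                peb.prior_mean, np.diag(var),
            )
            means.append(mr)
            log_evs.append(df)
        w = np.exp(log_evs - np.max(log_evs))
        w /= w.sum()
        assert w.sum() == pytest.approx(1.0)
        means = np.stack(means)
        flat_mean = bma.effect_mean.T.reshape(-1)
        for j in range(kp):
            assert means[:, j].min() - 1e-10 <= flat_mean[j] <= means[:, j].max() + 1e-10
        # and the weighted mean matches the independent enumeration
        np.testing.assert_allclose(flat_mean, w @ means, atol=1e-8)

    def test_exhaustive_cap_enforced(self, rng):
        peb = self._small_peb(np.array([[0.2, 0.1]]), 0.05, rng)
        with pytest.raises(ValueError, match="cap"):
            bma_search(peb, search="exhaustive", max_models=2)


class TestDecisionRule:
    @pytest.mark.parametrize(
        "mean,sd,prob,expected",
        [
            (0.2, 0.1, 0.95, "significant"),
            (0.1, 0.1, 0.88, "trend"),
            (0.0, 0.1, 0.50, "null"),
        ],
    )
    def test_labels(self, mean, sd, prob, expected):
        assert decision_rule(mean, sd, prob) == expected

    def test_ci_arithmetic(self):
        lo, hi = 0.2 - 1.6449 * 0.1, 0.2 + 1.6449 * 0.1
        assert lo == pytest.approx(0.0355, abs=1e-4)
        assert hi == pytest.approx(0.3645, abs=1e-4)
        assert lo > 0  # excludes zero

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            decision_rule(0.1, 0.0, 0.5)
        with pytest.raises(ValueError):
            decision_rule(0.1, 0.1, 1.5)
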