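import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spdcm.cohort import ParticipantRecord
from spdcm.srs import (
    SrsError,
    bh_fdr,
    fit_lmm_for_connections,
    fit_lmm_random_intercept,
    peb_srs_interaction,
    stratify_srs,
)


def _design(n, rng):
    x = np.column_stack(
        [np.ones(n), rng.standard_normal(n), rng.standard_normal(n), rng.standard_normal(n)]
    )
    return x, ["intercept", "SRS", "age", "FD"]


class TestLmm:
    def test_zero_site_variance_equals_ols(self, rng):
        n = 60
        x, names = _design(n, rng)
        y = x @ [1.0, 0.5, -0.3, 0.1] + rng.standard_normal(n)
        sites = [f"s{i % 3}" for i in range(n)]
        fit = fit_lmm_random_intercept(y, x, names, sites, force_zero_site_variance=True)
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        np.testing.assert_allclose(fit.terms["estimate"].to_numpy(), ols, atol=1e-8)

    def test_pure_site_shift_absorbed_by_random_intercept(self, rng):
        n = 80
        x, names = _design(n, rng)
        sites = np.array(["a"] * 40 + ["b"] * 40)
        # covariates centered within each site, so the +1 site shift lies
        # entirely in the span of the (random) site intercepts
        for half in (slice(0, 40), slice(40, 80)):
            x[half, 1:] -= x[half, 1:].mean(axis=0)
        beta = np.array([0.5, 0.4, -0.2, 0.0])
        noise = 0.3 * rng.standard_normal(n)
        y0 = x @ beta + noise
        y1 = y0 + np.where(sites == "b", 1.0, 0.0)
        fit0 = fit_lmm_random_intercept(y0, x, names, sites)
        fit1 = fit_lmm_random_intercept(y1, x, names, sites)
        est0 = fit0.terms.set_index("term")["estimate"]
        est1 = fit1.terms.set_index("term")["estimate"]
        for term in ("SRS", "age", "FD"):
            assert est1[term] == pytest.approx(est0[term], abs=1e-6)
        assert fit1.sigma2_site > 0

    def test_matches_statsmodels_mixedlm(self, rng):
        statsmodels = pytest.importorskip("statsmodels.api")
        n = 120
        x, names = _design(n, rng)
        sites = rng.integers(0, 5, n)
        y = (
            x @ [0.2, 0.3, -0.1, 0.05]
            + 0.4 * rng.standard_normal(5)[sites]
            + 0.5 * rng.standard_normal(n)
        )
        ours = fit_lmm_random_intercept(y, x, names, [f"s{k}" for k in sites])
        sm_fit = statsmodels.MixedLM(y, x, groups=sites).fit(reml=True)
        np.testing.assert_allclose(
            ours.terms["estimate"].to_numpy(), sm_fit.fe_params, atol=1e-4
        )
        np.testing.assert_allclose(
            ours.terms["se"].to_numpy(), sm_fit.bse_fe, rtol=0.02
        )
        assert ours.sigma2_site == pytest.approx(
            float(np.asarray(sm_fit.cov_re)[0, 0]), abs=0.02
        )

    def test_single_site_rejected(self, rng):
        x, names = _design(20, rng)
        with pytest.raises(SrsError, match="site"):
            fit_lmm_random_intercept(x[:, 1], x, names, ["a"] * 20)

    def test_singular_design_rejected(self, rng):
        n = 30
        x, names = _design(n, rng)
        x[:, 3] = x[:, 2]
        with pytest.raises(SrsError, match="singular"):
            fit_lmm_random_intercept(x[:, 1], x, names, ["a", "b"] * 15)


class TestBhFdr:
    def test_worked_example(self):
        q = bh_fdr([0.005, 0.03, 0.04, 0.2])
        np.testing.assert_allclose(q, [0.02, 0.0533, 0.0533, 0.2], atol=1e-3)

    def test_equal_p_values_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.07] * 5), [0.07] * 5)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_empty_rejected(self):
        with pytest.raises(SrsError):
            bh_fdr([])

    def test_out_of_range_rejected(self):
        with pytest.raises(SrsError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_step_up(self, p_list):
        # independent brute-force: q_i = min over j with p_j >= p_i of p_j*m/rank_j
        p = np.asarray(p_list)
        m = p.size
        order = np.argsort(p, kind="stable")
        brute = np.empty(m)
        adj = [p[order[j]] * m / (j + 1) for j in range(m)]
        for j in range(m):
            brute[order[j]] = min(1.0, min(adj[j:]))
        np.testing.assert_allclose(bh_fdr(p), brute, atol=1e-12)


class TestStratify:
    def _recs(self, srs_values):
        return [
            ParticipantRecord(f"s{i}", "TD", 20.0, 0.1, "a", srs_total=v)
            for i, v in enumerate(srs_values)
        ]

    def test_boundaries_inclusive_to_mid(self):
        strata = stratify_srs(self._recs([0.0, 50.0, 100.0]))
        assert set(strata.values()) == {"mid"}

    def test_extremes_assigned(self):
        strata = stratify_srs(self._recs([0.0, 10.0, 50.0, 90.0, 100.0]))
        assert strata["s0"] == "low" and strata["s4"] == "high"
        assert strata["s2"] == "mid"

    def test_location_invariance(self):
        vals = [3.0, 10.0, 55.0, 80.0, 120.0]
        s1 = stratify_srs(self._recs(vals))
        s2 = stratify_srs(self._recs([v + 40.0 for v in vals]))
        assert s1 == s2

    def test_zero_variance_rejected(self):
        with pytest.raises(SrsError, match="variance"):
            stratify_srs(self._recs([5.0, 5.0, 5.0]))


class TestPebSrs:
    def _cohort(self, rng, n=40, missing_every=4):
        recs, posts = [], []
        for i in range(n):
            srs = None if i % missing_every == 0 else float(rng.uniform(5, 150))
            recs.append(
                ParticipantRecord(
                    f"s{i:02d}", "ASD" if i % 2 else "TD",
                    float(rng.uniform(8, 40)), float(rng.uniform(0.05, 0.3)),
                    f"site{int(rng.integers(0, 3))}", srs_total=srs,
                )
            )
            posts.append((rng.normal(0, 0.2, 2), 0.01 * np.eye(2)))
        return recs, posts

    def test_missing_srs_rows_excluded(self, rng):
        recs, posts = self._cohort(rng)
        peb, bma = peb_srs_interaction(posts, recs, site_mode="none")
        n_complete = sum(r.srs_total is not None for r in recs)
        assert peb.design.n_subjects == n_complete
        assert peb.design.column_labels[:5] == ("mean", "SRS", "age", "SRS_x_age", "FD")

    def test_design_width_with_sites(self, rng):
        recs, posts = self._cohort(rng, n=60)
        n_sites = len({r.site for r in recs if r.srs_total is not None})
        peb, _ = peb_srs_interaction(posts, recs, site_mode="dummies")
        assert peb.design.n_covariates == 5 + (n_sites - 1)

    def test_no_srs_at_all_rejected(self, rng):
        recs, posts = self._cohort(rng, missing_every=1)
        with pytest.raises(SrsError):
            peb_srs_interaction(posts, recs)


class TestLmmPebConcordance:
    def test_srs_by_age_sign_agrees_between_lmm_and_peb(self):
        """With a strong negative SRS x age effect on one self-connection,
        the two-step LMM and the PEB variant agree in sign (and the PEB
        flags that cell) in at least 9 of 10 simulated cohorts."""
        from spdcm.synth import CohortSpec, sample_posterior_cohort

        labels = ("SubC", "A1", "V1")
        agree = 0
        flagged = 0
        for seed in range(10):
            spec = CohortSpec(
                n_per_group=(50, 50), n_sites=3, region_labels=labels,
                effect_table={("self_A1", "SRS_x_age"): -0.15},
                srs_missing_frac=0.0, seed=seed,
            )
            records, truth, posts = sample_posterior_cohort(spec)
            names = spec.mask().coupling_names()
            k = names.index("self_A1")
            strengths = pd.DataFrame(
                np.stack([m for m, _ in posts]),
                index=[r.subject_id for r in records], columns=names,
            )
            table = fit_lmm_for_connections(strengths, records)
            lmm_est = table[
                (table.connection == "self_A1") & (table.term == "SRS_x_age")
            ]["estimate"].iloc[0]
            peb, bma = peb_srs_interaction(
                posts, records, site_mode="none", connection_names=names
            )
            p_col = list(bma.covariate_names).index("SRS_x_age")
            peb_est = bma.effect_mean[k, p_col]
            if np.sign(lmm_est) == np.sign(peb_est) == -1:
                agree += 1
            if bma.significant[k, p_col]:
                flagged += 1
        assert agree >= 9
        assert flagged >= 9


class TestLmmTable:
    def test_q_values_attached_and_bounded_below_by_p(self, rng):
        n = 50
        recs = [
            ParticipantRecord(
                f"s{i:02d}", "TD", float(rng.uniform(8, 40)),
                float(rng.uniform(0.05, 0.3)), f"site{i % 3}",
                srs_total=float(rng.uniform(5, 150)),
            )
            for i in range(n)
        ]
        strengths = pd.DataFrame(
            rng.standard_normal((n, 3)),
            index=[r.subject_id for r in recs],
            columns=["c1", "c2", "c3"],
        )
        table = fit_lmm_for_connections(strengths, recs)
        tested = table[table["term"] == "SRS_x_age"]
        assert len(tested) == 3
        assert np.all(tested["q"].to_numpy() >= tested["p"].to_numpy() - 1e-12)
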