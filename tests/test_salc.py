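"""SALC mixture likelihood, EM estimation, class ordering and posteriors."""

import copy

import numpy as np
import pytest

import salcval as sv
from salcval.salc import (
    EMError,
    class_parameter_table,
    membership_odds_table,
    membership_prob,
    mixture_loglik,
    model_comparison_table,
    model_from_dict,
    model_to_dict,
)
from conftest import tiny_frame


def _toy_model(M=2, S=2, seed=0):
    rng = np.random.default_rng(seed)
    taste = [sv.TasteClassParams(rng.uniform(0.0, 0.15, 20), alpha=a)
             for a in np.linspace(0.1, 0.6, M)]
    _, names = sv.build_scale_design(
        np.array(["latent_pair"]), np.array([20.0]))
    scale = [sv.ScaleClassParams(
        np.concatenate([[g], rng.normal(0, 0.1, len(names) - 1)]), names=names)
        for g in np.linspace(0.5, 1.5, S)]
    member = sv.MembershipParams(
        delta=rng.normal(0, 0.3, (M - 1, 1)), theta=rng.normal(0, 0.3, (S - 1, 1)))
    return sv.SALCModel(taste, scale, member)


class TestMembershipProb:
    def test_zero_coefficients_uniform(self):
        p = membership_prob(np.zeros((2, 1)), np.ones((4, 1)), 3)
        np.testing.assert_allclose(p, 1.0 / 3.0)

    def test_two_class_closed_form(self):
        # non-reference intercept ln 2 -> (1/3, 2/3)
        p = membership_prob(np.array([[np.log(2.0)]]), np.ones((1, 1)), 2)
        np.testing.assert_allclose(p[0], [1 / 3, 2 / 3], rtol=1e-12)

    def test_coefficients_are_log_odds_ratios(self):
        """exp(delta_k) is the multiplicative effect of covariate k on the
        odds of the class versus the reference class."""
        delta = np.array([[0.3, np.log(0.532)]])
        z_off = np.array([[1.0, 0.0]])
        z_on = np.array([[1.0, 1.0]])
        odds = lambda z: (lambda p: p[0, 1] / p[0, 0])(membership_prob(delta, z, 2))
        assert odds(z_on) / odds(z_off) == pytest.approx(0.532, rel=1e-12)

    def test_simplex_and_mismatch(self):
        rng = np.random.default_rng(1)
        p = membership_prob(rng.normal(size=(2, 3)), rng.normal(size=(10, 3)), 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p >= 0).all()
        with pytest.raises(ValueError):
            membership_prob(np.zeros((2, 2)), np.ones((4, 1)), 3)


class TestRespondentLikelihood:
    def test_degenerate_mixture_equals_task_product(self, tiny_data):
        model = _toy_model(M=1, S=1)
        ll = sum(
            sv.loglik(
                sv.ChoiceData.from_frame(
                    tiny_frame()[lambda d: d["respondent_id"] == r]),
                model.taste_classes[0], model.scale_classes[0])
            for r in (1, 2, 3)
        )
        total, _, _ = mixture_loglik(tiny_data, model)
        assert total == pytest.approx(ll, rel=1e-10)

    def test_identical_components_collapse(self, tiny_data):
        one = _toy_model(M=1, S=1, seed=5)
        two = sv.SALCModel(
            [one.taste_classes[0], copy.deepcopy(one.taste_classes[0])],
            [one.scale_classes[0]],
            sv.MembershipParams(np.array([[0.7]]), np.zeros((0, 1))),
        )
        l1, _, _ = mixture_loglik(tiny_data, one)
        l2, _, _ = mixture_loglik(tiny_data, two)
        assert l2 == pytest.approx(l1, rel=1e-12)

    def test_brute_force_enumeration_oracle(self, tiny_data):
        """The vectorised mixture likelihood equals explicit enumeration over
        every (taste, scale) pair on a tiny fixture, to 1e-10."""
        model = _toy_model(M=2, S=2, seed=7)
        z3, _ = tiny_data.scale_design()
        pm = membership_prob(model.membership.delta, np.ones((3, 1)), 2)
        ps = membership_prob(model.membership.theta, np.ones((3, 1)), 2)
        expected = 0.0
        for i, rid in enumerate(tiny_data.resp_ids):
            mask = tiny_data.resp_ids[tiny_data.resp_idx] == rid
            acc = 0.0
            for m in range(2):
                for s in range(2):
                    prod = 1.0
                    for t in np.flatnonzero(mask):
                        mu = np.exp(model.scale_classes[s].gamma @ z3[t])
                        va = (1 - model.taste_classes[m].beta @ tiny_data.XA[t]) \
                            * tiny_data.TA[t] ** model.taste_classes[m].alpha
                        vb = (1 - model.taste_classes[m].beta @ tiny_data.XB[t]) \
                            * tiny_data.TB[t] ** model.taste_classes[m].alpha
                        p_a = 1.0 / (1.0 + np.exp(-mu * (va - vb)))
                        prod *= p_a if tiny_data.y[t] == 1 else 1 - p_a
                    acc += pm[i, m] * ps[i, s] * prod
            expected += np.log(acc)
        total, ll_i, _ = mixture_loglik(tiny_data, model)
        assert total == pytest.approx(expected, abs=1e-10)
        assert sv.respondent_likelihood(tiny_data, model, tiny_data.resp_ids[0]) \
            == pytest.approx(np.exp(ll_i[0]), rel=1e-10)

    def test_unknown_respondent(self, tiny_data):
        with pytest.raises(ValueError):
            sv.respondent_likelihood(tiny_data, _toy_model(1, 1), "nobody")


class TestPosterior:
    def test_valid_distributions(self, tiny_data):
        w = sv.posterior_membership(tiny_data, _toy_model(2, 2, seed=3))
        assert w.shape == (3, 2, 2)
        np.testing.assert_allclose(w.sum(axis=(1, 2)), 1.0, atol=1e-10)
        assert (w >= 0).all()

    def test_identical_classes_uniform_posterior(self, tiny_data):
        base = _toy_model(M=1, S=1, seed=9)
        model = sv.SALCModel(
            [base.taste_classes[0], copy.deepcopy(base.taste_classes[0])],
            [base.scale_classes[0], copy.deepcopy(base.scale_classes[0])],
            sv.MembershipParams(np.zeros((1, 1)), np.zeros((1, 1))),
        )
        w = sv.posterior_membership(tiny_data, model)
        np.testing.assert_allclose(w, 0.25, atol=1e-12)

    def test_hand_bayes_two_by_one(self, tiny_data):
        """Posterior for a 2x1 model matches an explicit Bayes computation."""
        model = _toy_model(M=2, S=1, seed=11)
        _, ll_i, w = mixture_loglik(tiny_data, model)
        pm = membership_prob(model.membership.delta, np.ones((3, 1)), 2)[0]
        # per-class conditional likelihood of respondent 1
        conds = []
        for m in range(2):
            sub = sv.SALCModel([model.taste_classes[m]], model.scale_classes,
                               sv.MembershipParams(np.zeros((0, 1)), np.zeros((0, 1))))
            _, lli, _ = mixture_loglik(tiny_data, sub)
            conds.append(np.exp(lli[0]))
        post = pm * conds / (pm @ conds)
        np.testing.assert_allclose(w[0, :, 0], post, atol=1e-12)


class TestEMFit:
    def test_salc11_matches_hcl(self, two_class_sim):
        data = two_class_sim["data"]
        hcl = sv.fit_hcl(data, compute_se=False)
        r = sv.em_fit(data, 1, 1, n_starts=1, seed=0)
        assert r.loglik == pytest.approx(hcl.loglik, abs=1e-6 * abs(hcl.loglik))
        assert r.n_params == hcl.n_params

    def test_em_ascent_and_convergence(self, two_class_sim):
        r = sv.em_fit(two_class_sim["data"], 2, 1, n_starts=3, seed=2,
                      intercept_only_scale=True)
        assert r.converged
        diffs = np.diff(r.loglik_trace)
        assert np.all(diffs >= -1e-6 * (1 + np.abs(r.loglik)))
        assert len(r.start_logliks) == 3

    def test_em_determinism(self, two_class_sim):
        kw = dict(n_starts=2, seed=7, intercept_only_scale=True, burn_in=5)
        a = sv.em_fit(two_class_sim["data"], 2, 1, **kw)
        b = sv.em_fit(two_class_sim["data"], 2, 1, **kw)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(
            a.model.taste_classes[0].beta, b.model.taste_classes[0].beta)

    def test_class_recovery_small(self, two_class_sim):
        """Two well-separated taste classes are recovered with near-perfect
        posterior assignment at n = 300."""
        r = sv.order_classes(sv.em_fit(
            two_class_sim["data"], 2, 1, n_starts=3, seed=3,
            intercept_only_scale=True))
        alphas = [t.alpha for t in r.model.taste_classes]
        assert alphas[0] == pytest.approx(0.1, abs=0.06)
        assert alphas[1] == pytest.approx(0.5, abs=0.08)
        hard = r.posterior.sum(axis=2).argmax(axis=1) + 1
        truth = two_class_sim["assignments"]["taste_class"].to_numpy()
        assert (hard == truth).mean() > 0.9

    def test_invalid_class_counts(self, tiny_data):
        with pytest.raises(ValueError):
            sv.em_fit(tiny_data, 0, 1)

    def test_posterior_shares_sum_to_100(self, two_class_sim):
        r = sv.em_fit(two_class_sim["data"], 2, 1, n_starts=2, seed=4,
                      intercept_only_scale=True, burn_in=5)
        assert r.taste_shares().sum() == pytest.approx(100.0)
        assert r.scale_shares().sum() == pytest.approx(100.0)


class TestOrderClasses:
    def test_already_ordered_unchanged(self):
        model = _toy_model(M=2, S=2)
        ordered = sv.order_classes(model)
        assert [t.alpha for t in ordered.taste_classes] == \
            [t.alpha for t in model.taste_classes]

    def test_permutation_restores_order_and_loglik(self, tiny_data):
        model = _toy_model(M=3, S=2, seed=13)
        ll0, _, _ = mixture_loglik(tiny_data, model)
        perm = [2, 0, 1]
        delta_full = np.vstack([np.zeros((1, 1)), model.membership.delta])[perm]
        shuffled = sv.SALCModel(
            [model.taste_classes[i] for i in perm],
            model.scale_classes,
            sv.MembershipParams(delta_full[1:] - delta_full[0],
                                model.membership.theta),
        )
        ll_shuf, _, _ = mixture_loglik(tiny_data, shuffled)
        assert ll_shuf == pytest.approx(ll0, abs=1e-12)
        restored = sv.order_classes(shuffled)
        ll_rest, _, _ = mixture_loglik(tiny_data, restored)
        assert ll_rest == pytest.approx(ll0, abs=1e-12)
        assert [t.alpha for t in restored.taste_classes] == \
            sorted(t.alpha for t in model.taste_classes)

    def test_scale_classes_sorted_by_intercept(self):
        model = _toy_model(M=2, S=2)
        g0 = [s.gamma[0] for s in sv.order_classes(model).scale_classes]
        assert g0 == sorted(g0)


class TestModelSearch:
    def test_singleton_grid_matches_hcl(self, two_class_sim):
        data = two_class_sim["data"]
        results = sv.model_search(data, M_grid=[1], S_grid=[1], n_starts=1, seed=0)
        assert len(results) == 1
        hcl = sv.fit_hcl(data, compute_se=False)
        assert results[0].loglik == pytest.approx(hcl.loglik, abs=1e-4)

    def test_ranking_stable_and_bic_ascending(self, two_class_sim):
        data = two_class_sim["data"]
        kw = dict(n_starts=2, seed=5, intercept_only_scale=True,
                  burn_in=5, n_polish=1)
        a = sv.model_search(data, M_grid=[1, 2], S_grid=[1], **kw)
        b = sv.model_search(data, M_grid=[1, 2], S_grid=[1], **kw)
        assert [r.bic for r in a] == [r.bic for r in b]
        bics = [r.bic for r in a if r.converged]
        assert bics == sorted(bics)
        table = model_comparison_table(a)
        assert set(table.columns) >= {"M", "S", "loglik", "n_params", "bic"}


class TestSerialization:
    def test_model_round_trip(self, tiny_data):
        model = _toy_model(M=2, S=2, seed=17)
        back = model_from_dict(model_to_dict(model))
        ll0, _, _ = mixture_loglik(tiny_data, model)
        ll1, _, _ = mixture_loglik(tiny_data, back)
        assert ll0 == ll1

    def test_report_tables(self, two_class_sim):
        r = sv.em_fit(two_class_sim["data"], 2, 1, n_starts=2, seed=6,
                      intercept_only_scale=True, burn_in=5, compute_se=True)
        ct = class_parameter_table(r)
        assert len(ct) == 2 * 21
        assert ct["std_error"].notna().all()
        mt = membership_odds_table(r)
        assert (mt["odds_ratio"] > 0).all()
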