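"""Link functions, priors and whole-relation likelihoods against independent oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from ddsbm.core import Assignment, ComponentParams, EntityGeometry, GriddedHyper, Relation
from ddsbm.likelihoods import (
    Dataset,
    beta_log_prior,
    eta_log_prior_logistic,
    joint_log_score,
    logistic_bernoulli_loglik,
    logistic_bernoulli_prob,
    logistic_poisson_loglik,
    logistic_poisson_rate,
    percomp_pmax_bernoulli_prob,
    relation_loglik,
    soma_depth_loglik,
    synapse_profile_loglik,
)
from ddsbm.priors import crp_log_prior, grid_log_prior


class TestLogisticBernoulli:
    def test_midpoint_is_half(self):
        for lam in (0.5, 2.0, 10.0):
            assert logistic_bernoulli_prob(7.0, 7.0, lam, 1.0, 0.0) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert logistic_bernoulli_prob(1e9, 10.0, 2.0, 0.9, 0.01) == pytest.approx(0.01)
        # far below threshold with steep slope -> ceiling
        assert logistic_bernoulli_prob(0.0, 100.0, 1.0, 0.9, 0.01) == pytest.approx(0.9)

    def test_scalar_matches_formula_oracle(self):
        # independent one-line evaluation of the printed link function
        mu, lam, d, pmax, pmin = 10.0, 2.0, 12.0, 0.9, 0.01
        pstar = 1.0 / (1.0 + math.exp((d - mu) / lam))
        expected = pstar * (pmax - pmin) + pmin
        assert logistic_bernoulli_prob(d, mu, lam, pmax, pmin) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_distance(self):
        d = np.linspace(0, 50, 200)
        p = logistic_bernoulli_prob(d, 20.0, 3.0, 0.95, 0.001)
        assert (np.diff(p) <= 0).all()

    def test_nonpositive_lam_rejected(self):
        with pytest.raises(ValueError):
            logistic_bernoulli_prob(1.0, 1.0, 0.0)

    def test_loglik_midpoint(self):
        assert logistic_bernoulli_loglik(1, 5.0, 5.0, 1.0, 1.0, 0.0) == pytest.approx(
            math.log(0.5)
        )

    def test_loglik_normalizes(self):
        ll0 = logistic_bernoulli_loglik(0, 3.0, 4.0, 1.5, 0.9, 0.05)
        ll1 = logistic_bernoulli_loglik(1, 3.0, 4.0, 1.5, 0.9, 0.05)
        assert math.exp(ll0) + math.exp(ll1) == pytest.approx(1.0, abs=1e-12)

    def test_loglik_matches_prob_on_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            d = rng.uniform(0, 30)
            mu = rng.uniform(0.1, 20)
            lam = rng.uniform(0.1, 10)
            pmax = rng.uniform(0.5, 1.0)
            pmin = rng.uniform(0, 0.1)
            p = logistic_bernoulli_prob(d, mu, lam, pmax, pmin)
            assert logistic_bernoulli_loglik(1, d, mu, lam, pmax, pmin) == pytest.approx(
                math.log(p)
            )
            assert logistic_bernoulli_loglik(0, d, mu, lam, pmax, pmin) == pytest.approx(
                math.log1p(-p)
            )

    def test_bad_observation_rejected(self):
        with pytest.raises(ValueError):
            logistic_bernoulli_loglik(2, 1.0, 1.0, 1.0)


class TestEtaPrior:
    def test_mode_at_zero(self):
        # exponential density is maximal at 0
        hp = 5.0
        expected = stats.expon.logpdf(0.0, scale=hp) + stats.expon.logpdf(1.0, scale=2.0)
        assert eta_log_prior_logistic(0.0, 1.0, hp, 2.0) == pytest.approx(expected)

    def test_density_integrates_to_one(self):
        hp = 3.0
        val, _ = integrate.quad(
            lambda x: math.exp(float(eta_log_prior_logistic(x, 1.0, hp, 2.0))
                               - float(stats.expon.logpdf(1.0, scale=2.0))),
            0, 50 * hp,
        )
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_hyperparameter_scaling_closed_form(self):
        # doubling the mean shifts the log-density by -log 2 + x/(2 hp) ... closed form
        x, hp = 4.0, 2.0
        base = float(eta_log_prior_logistic(x, 0.0, hp, 1.0))
        doubled = float(eta_log_prior_logistic(x, 0.0, 2 * hp, 1.0))
        assert doubled - base == pytest.approx(-math.log(2) + x / hp - x / (2 * hp))

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            eta_log_prior_logistic(-1.0, 1.0, 1.0, 1.0)


class TestLogisticPoisson:
    def test_midpoint_rate(self):
        r = logistic_poisson_rate(5.0, 5.0, 20.0, 1.0, 0.01)
        assert r == pytest.approx(0.5 * (20.0 - 0.01) + 0.01)

    def test_far_distance_floors_at_rmin(self):
        assert logistic_poisson_rate(1e9, 5.0, 20.0, 1.0, 0.01) == pytest.approx(0.01)

    def test_scalar_matches_formula_oracle(self):
        # cells averaging ~20 synapses when closer than 5 um
        mu, r_mn, d, lam, rmin = 5.0, 20.0, 2.0, 1.0, 0.01
        rstar = 1.0 / (1.0 + math.exp((d - mu) / lam))
        assert logistic_poisson_rate(d, mu, r_mn, lam, rmin) == pytest.approx(
            rstar * (r_mn - rmin) + rmin, rel=1e-12
        )

    def test_rate_must_exceed_floor(self):
        with pytest.raises(ValueError):
            logistic_poisson_rate(1.0, 1.0, 0.005, 1.0, 0.01)

    def test_count_zero_loglik_is_minus_rate(self):
        rate = logistic_poisson_rate(3.0, 5.0, 10.0, 2.0, 0.01)
        assert logistic_poisson_loglik(0, 3.0, 5.0, 10.0, 2.0, 0.01) == pytest.approx(-rate)

    def test_pmf_series_sums_to_one(self):
        # rate fixed at ~3 by choosing d = mu (r = (3.99+0.01)/2... pick directly)
        mu, r_mn, d, lam, rmin = 2.0, 5.99, 2.0, 1.0, 0.01
        rate = logistic_poisson_rate(d, mu, r_mn, lam, rmin)
        assert rate == pytest.approx(3.0)
        total = sum(
            math.exp(float(logistic_poisson_loglik(c, d, mu, r_mn, lam, rmin)))
            for c in range(201)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_monte_carlo_mean_matches_rate(self):
        rng = np.random.default_rng(11)
        rate = logistic_poisson_rate(1.0, 4.0, 12.0, 2.0, 0.01)
        draws = rng.poisson(rate, size=100_000)
        se = math.sqrt(rate / draws.size)
        assert abs(draws.mean() - rate) < 3 * se

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            logistic_poisson_loglik(-1, 1.0, 1.0, 2.0, 1.0)


class TestPercompCeiling:
    def test_midpoint_between_floor_and_ceiling(self):
        p = percomp_pmax_bernoulli_prob(8.0, 0.6, 8.0, 2.0, 0.01)
        assert p == pytest.approx(0.5 * (0.6 - 0.01) + 0.01)

    def test_uniform_beta_prior_is_flat(self):
        for p in (0.1, 0.5, 0.9):
            assert float(beta_log_prior(p, 1.0, 1.0)) == pytest.approx(0.0)

    def test_beta_prior_integrates_to_one(self):
        val, _ = integrate.quad(
            lambda p: math.exp(float(beta_log_prior(p, 2.0, 0.5))), 0, 1
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_ceiling_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            percomp_pmax_bernoulli_prob(1.0, 1.5, 1.0, 1.0)


class TestSomaDepth:
    HP = dict(mu_hp=0.4, kappa_hp=2.0, sigma2_hp=0.05, nu_hp=3.0)

    def test_empty_type_scores_zero(self):
        assert soma_depth_loglik([], **self.HP) == 0.0

    def test_single_point_matches_numerical_integration(self):
        # integrate the NIX prior x normal likelihood over (mean, variance)
        # on a dense grid covering essentially all prior mass
        x0 = 0.55
        hp = self.HP
        nu, t2 = hp["nu_hp"], hp["sigma2_hp"]
        m = np.linspace(-4, 5, 3000)[:, None]
        s2 = np.exp(np.linspace(np.log(1e-5), np.log(50), 3000))[None, :]
        prior_m = stats.norm.pdf(m, hp["mu_hp"], np.sqrt(s2 / hp["kappa_hp"]))
        log_s2 = ((nu / 2) * math.log(nu * t2 / 2) - math.lgamma(nu / 2)
                  - (nu / 2 + 1) * np.log(s2) - nu * t2 / (2 * s2))
        joint = prior_m * np.exp(log_s2) * stats.norm.pdf(x0, m, np.sqrt(s2))
        val = np.trapezoid(np.trapezoid(joint, s2[0], axis=1), m[:, 0])
        assert soma_depth_loglik([x0], **self.HP) == pytest.approx(math.log(val), abs=1e-3)

    def test_add_then_remove_is_identity(self):
        depths = [0.2, 0.3, 0.25]
        base = soma_depth_loglik(depths, **self.HP)
        assert soma_depth_loglik(list(depths), **self.HP) == pytest.approx(base)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 9)
        assert soma_depth_loglik(x, **self.HP) == pytest.approx(
            soma_depth_loglik(x[::-1], **self.HP)
        )

    def test_chain_rule_consistency(self):
        # marginal factorizes into sequential posterior predictives
        x = [0.1, 0.6, 0.4]
        full = soma_depth_loglik(x, **self.HP)
        seq = sum(
            soma_depth_loglik(x[: i + 1], **self.HP) - soma_depth_loglik(x[:i], **self.HP)
            for i in range(3)
        )
        assert full == pytest.approx(seq)


class TestSynapseProfile:
    def test_single_mode_reduces_to_gaussian(self):
        pts = np.array([0.2, 0.5, 0.8])
        got = synapse_profile_loglik(pts, [0.4], [1.0], 0.05)
        expected = stats.norm.logpdf(pts, 0.4, math.sqrt(0.05)).sum()
        assert got == pytest.approx(expected)

    def test_duplicating_points_doubles_loglik(self):
        pts = np.array([0.1, 0.9])
        one = synapse_profile_loglik(pts, [0.3, 0.7], [0.6, 0.4], 0.02)
        two = synapse_profile_loglik(np.tile(pts, 2), [0.3, 0.7], [0.6, 0.4], 0.02)
        assert two == pytest.approx(2 * one)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = rng.integers(1, 4)
            means = rng.uniform(0, 1, m)
            w = rng.dirichlet(np.ones(m))
            s2 = rng.uniform(0.01, 0.5)
            pts = rng.uniform(0, 1, rng.integers(1, 8))
            expected = sum(
                math.log(sum(wi * stats.norm.pdf(x, mi, math.sqrt(s2))
                             for wi, mi in zip(w, means)))
                for x in pts
            )
            assert synapse_profile_loglik(pts, means, w, s2) == pytest.approx(expected)

    def test_too_many_modes_rejected(self):
        with pytest.raises(ValueError):
            synapse_profile_loglik([0.5], [0.1, 0.2, 0.3, 0.4], [0.25] * 4, 0.1)


def _tiny_hyper():
    return GriddedHyper(
        {"mu_hp": np.array([5.0]), "lam_hp": np.array([2.0]),
         "p_max": np.array([0.9]), "p_min": np.array([0.01])}
    )


class TestRelationLoglik:
    def test_fully_masked_is_zero(self):
        n = 4
        rel = Relation(np.zeros((n, n), dtype=int), mask=np.zeros((n, n), dtype=bool))
        geom = EntityGeometry(np.arange(n, dtype=float)[:, None])
        params = ComponentParams({"mu": np.array([[3.0]]), "lam": np.array([[1.0]])})
        assert relation_loglik(rel, geom, Assignment(np.zeros(n, dtype=int)),
                               params, _tiny_hyper()) == 0.0

    def test_three_node_hand_summed(self):
        matrix = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        pos = np.array([[0.0], [1.0], [3.0]])
        rel = Relation(matrix)
        geom = EntityGeometry(pos)
        params = ComponentParams({"mu": np.array([[2.0]]), "lam": np.array([[1.0]])})
        got = relation_loglik(rel, geom, Assignment([0, 0, 0]), params, _tiny_hyper())
        expected = 0.0
        for (i, j, obs) in [(0, 1, 1), (0, 2, 0), (1, 2, 1)]:
            d = abs(pos[i, 0] - pos[j, 0])
            p = (1 / (1 + math.exp((d - 2.0) / 1.0))) * (0.9 - 0.01) + 0.01
            expected += math.log(p) if obs else math.log1p(-p)
        assert got == pytest.approx(expected)

    def test_entity_permutation_invariance(self):
        rng = np.random.default_rng(2)
        n = 6
        matrix = rng.integers(0, 2, (n, n))
        matrix = np.triu(matrix, 1)
        matrix += matrix.T
        pos = rng.uniform(0, 10, (n, 2))
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        params = ComponentParams({"mu": np.array([[4.0, 1.0], [1.0, 6.0]]),
                                  "lam": np.ones((2, 2)) * 2.0})
        base = relation_loglik(Relation(matrix), EntityGeometry(pos),
                               Assignment(labels), params, _tiny_hyper())
        perm = rng.permutation(n)
        got = relation_loglik(
            Relation(matrix[np.ix_(perm, perm)]), EntityGeometry(pos[perm]),
            Assignment(labels[perm]), params, _tiny_hyper())
        assert got == pytest.approx(base)

    def test_double_loop_oracle_small_instances(self):
        # literal pairwise loop over all observed off-diagonal pairs
        rng = np.random.default_rng(9)
        hyper = _tiny_hyper()
        for n in (3, 5, 8):
            for directed in (False, True):
                matrix = rng.integers(0, 2, (n, n))
                mask = rng.random((n, n)) < 0.8
                if not directed:
                    matrix = np.triu(matrix, 1)
                    matrix += matrix.T
                    mask = mask & mask.T
                pos = rng.uniform(0, 10, (n, 2))
                k = 3
                labels = rng.integers(0, k, n)
                labels[:k] = np.arange(k)
                mu = rng.uniform(1, 8, (k, k))
                lam = rng.uniform(0.5, 3, (k, k))
                if not directed:
                    mu = np.triu(mu) + np.triu(mu, 1).T
                    lam = np.triu(lam) + np.triu(lam, 1).T
                rel = Relation(matrix, directed=directed, mask=mask)
                geom = EntityGeometry(pos)
                got = relation_loglik(rel, geom, Assignment(labels),
                                      ComponentParams({"mu": mu, "lam": lam}), hyper)
                expected = 0.0
                for i in range(n):
                    js = range(n) if directed else range(i + 1, n)
                    for j in js:
                        if i == j or not mask[i, j]:
                            continue
                        p = logistic_bernoulli_prob(
                            geom.distances[i, j], mu[labels[i], labels[j]],
                            lam[labels[i], labels[j]], 0.9, 0.01)
                        expected += math.log(p) if matrix[i, j] else math.log1p(-p)
                assert got == pytest.approx(expected), f"n={n} directed={directed}"


class TestJointScore:
    def _small_state(self, rng, n=6, k=2):
        from ddsbm.inference import InferenceConfig, init_state
        from ddsbm.synthetic import gen_dd_sbm

        rel, geom, _ = gen_dd_sbm(n, k, seed=int(rng.integers(1 << 16)), box=10.0)
        data = Dataset([rel], geom)
        cfg = InferenceConfig(n_iters_anneal=1, n_iters_post=0, n_chains=1)
        state = init_state(data, cfg, rng)
        state.temperature = 1.0
        return data, state

    def test_single_relation_composition(self):
        from ddsbm.likelihoods import get_obs_model

        rng = np.random.default_rng(21)
        data, state = self._small_state(rng)
        lik = relation_loglik(data.relations[0], data.geometry, state.assignment,
                              state.component_params[0], state.hyper[0])
        om = get_obs_model(data.models[0])
        lp = om.param_log_prior(state.component_params[0].tables, state.hyper[0])
        priors = (float(np.sum(np.triu(lp))) + grid_log_prior(state.hyper[0])
                  + crp_log_prior(state.assignment, state.alpha.current("alpha"))
                  + grid_log_prior(state.alpha))
        assert joint_log_score(data, state) == pytest.approx(lik + priors)

    def test_two_identical_relations_double_likelihood(self):
        import copy

        rng = np.random.default_rng(22)
        data, state = self._small_state(rng)
        rel = data.relations[0]
        data2 = Dataset([rel, rel], data.geometry,
                        models=[data.models[0], data.models[0]])
        state2 = copy.deepcopy(state)
        state2.component_params = [state.component_params[0],
                                   copy.deepcopy(state.component_params[0])]
        state2.hyper = [state.hyper[0], copy.deepcopy(state.hyper[0])]
        one = joint_log_score(data, state)
        two = joint_log_score(data2, state2)
        lik = relation_loglik(rel, data.geometry, state.assignment,
                              state.component_params[0], state.hyper[0])
        # second relation adds one likelihood copy + one prior copy
        from ddsbm.likelihoods import get_obs_model

        om = get_obs_model(data.models[0])
        lp = om.param_log_prior(state.component_params[0].tables, state.hyper[0])
        prior_extra = float(np.sum(np.triu(lp))) + grid_log_prior(state.hyper[0])
        assert two - one == pytest.approx(lik + prior_extra)

    def test_term_by_term_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        data, state = self._small_state(rng, n=6)
        rel = data.relations[0]
        c = state.assignment.labels
        mu = state.component_params[0].tables["mu"]
        lam = state.component_params[0].tables["lam"]
        h = state.hyper[0]
        pmax, pmin = h.current("p_max"), h.current("p_min")
        lik = 0.0
        for i in range(rel.n):
            for j in range(i + 1, rel.n):
                p = logistic_bernoulli_prob(data.geometry.distances[i, j],
                                            mu[c[i], c[j]], lam[c[i], c[j]], pmax, pmin)
                p = min(max(p, 1e-12), 1 - 1e-12)
                lik += math.log(p) if rel.matrix[i, j] else math.log1p(-p)
        prior = 0.0
        k = state.assignment.k
        for m in range(k):
            for n_ in range(m, k):
                prior += float(eta_log_prior_logistic(
                    mu[m, n_], lam[m, n_], h.current("mu_hp"), h.current("lam_hp")))
        prior += grid_log_prior(h)
        prior += crp_log_prior(state.assignment, state.alpha.current("alpha"))
        prior += grid_log_prior(state.alpha)
        assert joint_log_score(data, state) == pytest.approx(lik + prior)

    def test_label_permutation_invariance(self):
        import copy

        rng = np.random.default_rng(24)
        data, state = self._small_state(rng, n=8, k=3)
        base = joint_log_score(data, state)
        k = state.assignment.k
        perm = np.random.default_rng(1).permutation(k)
        state2 = copy.deepcopy(state)
        state2.assignment = Assignment(perm[state.assignment.labels])
        # permute tables consistently: new[perm[m], perm[n]] = old[m, n]
        inv = np.argsort(perm)
        for name, tab in state.component_params[0].tables.items():
            state2.component_params[0].tables[name] = tab[np.ix_(inv, inv)]
        assert joint_log_score(data, state2) == pytest.approx(base)

    def test_temperature_divides_likelihood_only(self):
        rng = np.random.default_rng(25)
        data, state = self._small_state(rng)
        s1 = joint_log_score(data, state, temperature=1.0)
        s4 = joint_log_score(data, state, temperature=4.0)
        lik = relation_loglik(data.relations[0], data.geometry, state.assignment,
                              state.component_params[0], state.hyper[0])
        assert s1 - s4 == pytest.approx(lik - lik / 4.0)
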