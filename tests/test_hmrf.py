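import math

import networkx as nx
import numpy as np
import pytest
from scipy import integrate, special

from rewireprio import (
    HMRFConfig,
    HMRFPrioritizer,
    HMRFState,
    association_potential,
    compute_h,
    conditional_posterior,
    discrimination_ability,
    evidence_densities,
    evidence_log_ratio,
    icm_fit,
    init_labels,
    normal_scores,
    rank_genes,
)

from ._oracles import ising_conditional_oracle, quantile_oracle


def make_state(gene_ids, xi, omega, h=0.0, potential=None):
    xi = np.asarray(xi, dtype=float)
    omega = np.asarray(omega, dtype=int)
    if potential is None:
        potential = np.zeros_like(xi)
    return HMRFState(gene_ids=list(gene_ids), xi=xi, omega=omega,
                     potential=potential, h=h, posterior=np.zeros_like(xi),
                     n_sweeps=0, converged=True)


class TestNormalScores:
    def test_median_p_gives_zero(self):
        assert normal_scores([0.5])[0] == pytest.approx(0.0)

    def test_p_0025_gives_upper_tail_quantile(self):
        assert normal_scores([0.025])[0] == pytest.approx(1.959964, abs=1e-5)

    def test_p_zero_clamped_finite(self):
        xi = normal_scores([0.0], clamp=1e-4)[0]
        assert np.isfinite(xi)
        assert xi == pytest.approx(special.ndtri(1 - 1e-4))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            normal_scores([1.5])


class TestInitLabels:
    def test_threshold_inclusive(self):
        assert init_labels([0.005])[0] == 1

    def test_marginal_gene_starts_negative(self):
        assert init_labels([0.008])[0] == -1

    def test_all_strong_all_positive(self):
        assert (init_labels([0.001, 0.005, 0.0]) == 1).all()

    def test_unfiltered_pvalue_is_pipeline_misuse(self):
        with pytest.raises(ValueError, match="MV filter"):
            init_labels([0.02])


class TestAssociationPotential:
    def _net(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        g.add_edge("a", "b", weight=0.5)
        return g

    def test_isolated_gene_zero(self):
        pot = association_potential(self._net(), [1, 1, 1])
        assert pot[2] == 0.0

    def test_positive_neighbor_tau1_term(self):
        pot = association_potential(self._net(), [-1, 1, 1], HMRFConfig(tau1=0.01))
        assert pot[0] == pytest.approx(0.01 * 0.5)

    def test_weak_negative_neighbor_contributes_nothing(self):
        # weight 0.5 < delta=0.95 so the tau2 sum is empty
        pot = association_potential(self._net(), [1, -1, 1], HMRFConfig())
        assert pot[0] == 0.0

    def test_strong_negative_neighbor_tau2_term(self):
        g = self._net()
        g["a"]["b"]["weight"] = 0.97
        pot = association_potential(g, [1, -1, 1], HMRFConfig(tau2=0.01))
        assert pot[0] == pytest.approx(0.01 * 0.97)


class TestComputeH:
    def test_all_zero_potentials(self):
        assert compute_h(np.zeros(10)) == 0.0

    def test_linear_interpolation_matches_sort_oracle(self):
        pot = 0.01 * np.arange(1, 101)
        assert compute_h(pot, 0.90) == pytest.approx(quantile_oracle(pot, 0.90))

    def test_q_one_is_maximum(self, rng):
        pot = rng.uniform(size=37)
        assert compute_h(pot, 1.0) == pytest.approx(pot.max())

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError):
            compute_h([])


class TestEvidenceDensities:
    def test_null_density_standard_normal_at_zero(self):
        f0, _ = evidence_densities(0.0)
        assert f0 == pytest.approx(1.0 / math.sqrt(2 * math.pi))

    def test_alternative_is_student_t_closed_form(self):
        """f1 equals the non-standardized t density written out by hand."""
        cfg = HMRFConfig(mu_bar=2.0, a=1.0, g=1.0, d=1.0)
        nu, loc = cfg.g, cfg.mu_bar
        s2 = cfg.d * (1 + 1 / cfg.a)
        for xi in (-1.0, 0.0, 2.0, 3.7):
            z = (xi - loc) ** 2 / (nu * s2)
            expected = (
                math.gamma((nu + 1) / 2)
                / (math.gamma(nu / 2) * math.sqrt(math.pi * nu * s2))
                * (1 + z) ** (-(nu + 1) / 2)
            )
            assert evidence_densities(xi, cfg)[1] == pytest.approx(expected, rel=1e-12)

    def test_alternative_integrates_to_one(self):
        cfg = HMRFConfig(mu_bar=2.0, a=1.0, g=3.0, d=1.0)
        total, _ = integrate.quad(lambda t: evidence_densities(t, cfg)[1], -300, 300)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_nonfinite_score_rejected(self):
        with pytest.raises(ValueError):
            evidence_densities(float("inf"))


class TestConditionalPosterior:
    def test_branches_sum_to_one(self, rng):
        """P(+1|.) and P(-1|.) computed independently add to 1."""
        g = nx.Graph()
        g.add_edge(0, 1, weight=0.8)
        cfg = HMRFConfig()
        state = make_state([0, 1], xi=[1.0, -0.5], omega=[1, -1], h=0.3)
        p_plus = conditional_posterior(0, state, g, cfg)
        base = evidence_log_ratio(state.xi, cfg) - state.h
        q = base[0] + cfg.tau1 * 0.0  # neighbor 1 is labeled -1, weight < delta
        p_minus = 1.0 / (1.0 + math.exp(q))
        assert p_plus + p_minus == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_evidence(self):
        """Posterior is non-decreasing in xi over the candidate range
        (xi >= Phi^-1(0.99), since every candidate has p_mv <= 0.01); for
        strongly negative xi the heavy-tailed t alternative makes the
        likelihood ratio non-monotone, but screened genes never get there."""
        g = nx.Graph()
        g.add_nodes_from([0])
        cfg = HMRFConfig()
        post = [
            conditional_posterior(0, make_state([0], [xi], [1], h=0.0), g, cfg)
            for xi in np.linspace(special.ndtri(0.99), 8, 25)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(post, post[1:]))
        assert post[-1] > 0.999

    def test_matches_ising_enumeration(self, rng):
        """Closed-form conditional equals the explicit-Z enumeration of the
        joint (Ising prior x evidence), for every node of random graphs."""
        cfg = HMRFConfig(tau1=0.6, tau2=0.8, delta=0.7, mu_bar=1.5, g=2.0)
        for _ in range(10):
            m = int(rng.integers(2, 8))
            g = nx.Graph()
            g.add_nodes_from(range(m))
            for u in range(m):
                for v in range(u + 1, m):
                    if rng.random() < 0.5:
                        g.add_edge(u, v, weight=float(rng.uniform(0.3, 1.0)))
            xi = rng.normal(size=m)
            omega = rng.choice([-1, 1], size=m)
            h = float(rng.uniform(0, 1))
            state = make_state(range(m), xi, omega, h=h)
            edges = [(u, v, d["weight"]) for u, v, d in g.edges(data=True)]
            log_f0 = [math.log(evidence_densities(x, cfg)[0]) for x in xi]
            log_f1 = [math.log(evidence_densities(x, cfg)[1]) for x in xi]
            for p in range(m):
                expected = ising_conditional_oracle(
                    edges, m, p, omega, h=h, tau1=cfg.tau1, tau2=cfg.tau2,
                    delta=cfg.delta, log_f0=log_f0, log_f1=log_f1,
                )
                assert conditional_posterior(p, state, g, cfg) == pytest.approx(
                    expected, abs=1e-10
                )


class TestICM:
    def _candidate_ps(self, rng, m):
        # candidate p-values on the MV lattice, all <= 0.01
        return rng.choice([0.0, 0.002, 0.004, 0.006, 0.008, 0.01], size=m)

    def test_empty_edges_gives_independent_posteriors(self, rng):
        m = 6
        g = nx.Graph()
        g.add_nodes_from(range(m))
        p = self._candidate_ps(rng, m)
        cfg = HMRFConfig()
        state = icm_fit(g, p, cfg, gene_ids=range(m), k_perms=500)
        base = evidence_log_ratio(state.xi, cfg) - state.h
        assert np.allclose(state.posterior, special.expit(base), atol=1e-12)

    def test_symmetric_pair_symmetric_posteriors(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.6)
        state = icm_fit(g, [0.004, 0.004], HMRFConfig(), gene_ids=["a", "b"],
                        k_perms=500)
        assert state.posterior[0] == pytest.approx(state.posterior[1])

    def test_converges_and_is_conditional_mode_fixed_point(self, rng):
        """At convergence every label is the mode of its own conditional."""
        for _ in range(10):
            m = int(rng.integers(3, 20))
            g = nx.Graph()
            g.add_nodes_from(range(m))
            for u in range(m):
                for v in range(u + 1, m):
                    if rng.random() < 0.3:
                        g.add_edge(u, v, weight=float(rng.uniform(0.01, 1.0)))
            p = self._candidate_ps(rng, m)
            cfg = HMRFConfig(tau1=0.5, tau2=0.5)
            state = icm_fit(g, p, cfg, gene_ids=range(m), k_perms=500)
            assert state.converged and state.n_sweeps <= cfg.max_sweeps
            for i in range(m):
                post = conditional_posterior(i, state, g, cfg)
                if state.omega[i] == 1:
                    assert post >= 0.5
                else:
                    assert post < 0.5

    def test_posterior_monotone_in_own_evidence(self, rng):
        g = nx.Graph()
        g.add_edge(0, 1, weight=0.5)
        g.add_nodes_from([2, 3])
        base_p = np.array([0.006, 0.004, 0.008, 0.002])
        cfg = HMRFConfig()
        post = []
        for p0 in (0.01, 0.006, 0.002, 0.0):
            p = base_p.copy()
            p[0] = p0
            state = icm_fit(g, p, cfg, gene_ids=range(4), k_perms=500)
            post.append(state.posterior[0])
        assert all(b >= a - 1e-12 for a, b in zip(post, post[1:]))

    def test_deterministic_under_same_inputs(self, rng):
        g = nx.Graph()
        g.add_nodes_from(range(5))
        g.add_edge(0, 1, weight=0.99)
        g.add_edge(1, 2, weight=0.4)
        p = self._candidate_ps(rng, 5)
        a = icm_fit(g, p, HMRFConfig(), gene_ids=range(5), k_perms=500)
        b = icm_fit(g, p, HMRFConfig(), gene_ids=range(5), k_perms=500)
        assert np.array_equal(a.posterior, b.posterior)
        assert np.array_equal(a.omega, b.omega)

    def test_planted_signal_outranks_null(self, small_dataset):
        """Full screening-to-posterior chain: planted genes' mean posterior
        exceeds null genes' on defaults."""
        from rewireprio import (
            build_wgdcn,
            filter_candidates,
            gcc_by_condition,
            mv_screen_matrix,
        )
        from rewireprio.io import binary_response

        expr, meta, truth = small_dataset
        y = binary_response(meta, expr.sample_ids)
        res = mv_screen_matrix(expr.values, y, expr.gene_ids, k_perms=500, seed=11)
        cand = filter_candidates(res)
        sub = expr.subset_genes(cand)
        gt, gc = gcc_by_condition(sub, y)
        net = build_wgdcn(gt, gc, cand)
        pvals = res.set_index("gene_id").loc[cand, "p_mv"].to_numpy()
        state = icm_fit(net, pvals, HMRFConfig(), gene_ids=cand, k_perms=500)
        cls = truth.set_index("gene_id")["class"]
        planted = [i for i, g in enumerate(cand) if cls[g] != "null"]
        null = [i for i, g in enumerate(cand) if cls[g] == "null"]
        assert planted
        if null:
            assert state.posterior[planted].mean() > state.posterior[null].mean()


class TestRanking:
    def test_distinct_posteriors_strict_order(self):
        state = make_state("abc", xi=[1, 2, 3], omega=[1, 1, 1])
        state.posterior = np.array([0.2, 0.9, 0.5])
        ranked = rank_genes(state, top_k=3)
        assert ranked["gene_id"].tolist() == ["b", "c", "a"]
        assert ranked["rank"].tolist() == [1, 2, 3]

    def test_full_tie_breaks_lexicographically(self):
        state = make_state(["z", "m", "a"], xi=[1.0, 1.0, 1.0], omega=[1, 1, 1])
        state.posterior = np.array([0.5, 0.5, 0.5])
        ranked = rank_genes(state, top_k=3)
        assert ranked["gene_id"].tolist() == ["a", "m", "z"]

    def test_xi_breaks_posterior_ties_first(self):
        state = make_state(["a", "b"], xi=[1.0, 2.0], omega=[1, 1])
        state.posterior = np.array([0.5, 0.5])
        assert rank_genes(state, top_k=2)["gene_id"].tolist() == ["b", "a"]

    def test_topk_beyond_m_warns_and_returns_all(self):
        state = make_state("ab", xi=[1, 2], omega=[1, 1])
        with pytest.warns(UserWarning, match="exceeds"):
            ranked = rank_genes(state, top_k=20)
        assert len(ranked) == 2


class TestDiscriminationAbility:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([0.1, 0.2, 0.3], 1.0),
            ([0.5, 0.5, 0.5, 0.5], 0.25),
            ([0.1, 0.1, 0.2, 0.3], 0.75),
        ],
    )
    def test_unique_fraction(self, scores, expected):
        assert discrimination_ability(scores) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            discrimination_ability([])


class TestHMRFPrioritizerEstimator:
    def test_fit_and_top_genes(self):
        import pandas as pd

        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        g.add_edge("a", "b", weight=0.8)
        p = pd.Series([0.001, 0.004, 0.01], index=["a", "b", "c"])
        est = HMRFPrioritizer(k_perms=500).fit(g, p)
        assert est.posterior_.shape == (3,)
        assert set(est.labels_) <= {-1, 1}
        assert len(est.top_genes(2)) == 2

    def test_params_round_trip(self):
        from sklearn.base import clone

        est = HMRFPrioritizer(tau1=0.05, mu_bar=3.0)
        assert clone(est).get_params() == est.get_params()
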