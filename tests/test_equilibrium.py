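"""Migration-drift-equilibrium analysis."""

import math

import numpy as np
import pytest

from metapopne import (
    PopulationModel,
    make_island,
    solve_equilibrium,
    fst_eq,
    fst_eq_approx,
    fst_eq_approx_island,
    harmonic_size_island,
    ii_inf,
    ii_inf_limit,
    ii_inf_approx_symmetric,
    ii_inf_approx_island,
    make_ii_tau,
    ne_eq,
    tau_max,
    island_ne_v_eq,
    local_weights,
    uniform_weights,
    reproductive_weights,
    exact_chain,
)


class TestSolveEquilibrium:
    def test_wright_fisher(self):
        N = 40
        m = PopulationModel(B=np.ones((1, 1)), Nc=[N], Ne=[N])
        st = solve_equilibrium(m)
        assert st.lam == pytest.approx(1 - 1 / (2 * N), rel=1e-12)
        assert st.NeE == pytest.approx(N, rel=1e-12)

    def test_eigenpair_residual_and_positivity(self, fig1_model, fig1_state):
        from metapopne import build_A

        A = build_A(fig1_model)
        st = fig1_state
        assert np.max(np.abs(A @ st.r - st.lam * st.r)) < 1e-10
        assert np.all(st.r > 0)
        assert st.r.sum() == pytest.approx(1.0)

    def test_matches_third_eigenvalue_of_exact_chain(self):
        # the pair-coancestry eigenvalue equals the largest non-unit
        # eigenvalue of the exact joint allele-frequency Markov chain
        m = make_island(2, 0.3, 2, 2)
        st = solve_equilibrium(m)
        P, _ = exact_chain(m)
        ev = np.sort(np.linalg.eigvals(P).real)[::-1]
        assert ev[0] == pytest.approx(1.0, abs=1e-10)
        assert ev[1] == pytest.approx(1.0, abs=1e-10)
        assert ev[2] == pytest.approx(st.lam, abs=1e-10)


class TestFstEq:
    def test_single_deme_rejected(self):
        m = PopulationModel(B=np.ones((1, 1)), Nc=[10], Ne=[10])
        st = solve_equilibrium(m)
        with pytest.raises(ValueError):
            fst_eq(st, np.ones(1))

    def test_island_approximation_within_5_percent(self, fig1_state):
        exact = fst_eq(fig1_state, uniform_weights(10))
        approx = fst_eq_approx_island(10, 0.1, 50, 50)
        assert approx == pytest.approx(9 / (2 * 10 * 50 * 0.19), rel=1e-12)
        assert exact == pytest.approx(approx, rel=0.05)

    def test_panmixia_limit(self):
        st = solve_equilibrium(make_island(5, 1.0, 5000, 5000))
        assert fst_eq(st, uniform_weights(5)) == pytest.approx(0.0, abs=1e-3)

    def test_general_formula_reduces_to_island_shortcut(self):
        s, m, Nc, Ne = 10, 0.3, 80.0, 40.0
        eta = np.concatenate([[1.0], np.full(s - 1, 1 - m)])
        general = fst_eq_approx(eta, Nc, Ne, s)
        # the island shortcut replaces the eigenvalue mean by the harmonic
        # size; the two are algebraically identical
        assert general == pytest.approx(fst_eq_approx_island(s, m, Nc, Ne), rel=1e-12)

    def test_scale_invariance_in_r(self, fig1_state):
        import dataclasses

        w = uniform_weights(10)
        scaled = dataclasses.replace(fig1_state, r=fig1_state.r * 37.0)
        assert fst_eq(scaled, w) == pytest.approx(fst_eq(fig1_state, w), rel=1e-14)


class TestIIInf:
    def test_reproductive_weights_give_zero(self, fig1_state):
        g = fig1_state.gamma
        for tau in (1, 5, 100, math.inf):
            assert abs(ii_inf(fig1_state, g, g, tau)) < 1e-12

    def test_island_tau1_approximation(self, fig1_state, e1):
        exact = ii_inf(fig1_state, e1, e1, 1)
        approx = ii_inf_approx_island(10, 0.1, 50, 50, e1, e1, 1)
        assert approx == pytest.approx((0.9 - 0.9 * 0.9) / (50 * 0.19), rel=1e-12)
        assert exact == pytest.approx(approx, rel=0.05)

    def test_symmetric_eigenbasis_equals_island_shortcut(self):
        m = make_island(6, 0.4, 60, 30)
        w = local_weights(6, 2)
        v = uniform_weights(6)
        for tau in (1, 3, 10):
            a = ii_inf_approx_symmetric(m, w, v, tau)
            b = ii_inf_approx_island(6, 0.4, 60, 30, w, v, tau)
            assert a == pytest.approx(b, rel=1e-12, abs=1e-15)

    def test_limit_consistent_with_caption_product(self, fig1_state, e1):
        II = ii_inf_limit(fig1_state, e1)
        assert math.log(1 / II) * 2 * fig1_state.NeE == pytest.approx(2432.8, abs=0.05)


class TestNeEq:
    def test_reproductive_weights_recover_NeE_all_flavours(self, fig1_state):
        ii = make_ii_tau(fig1_state, fig1_state.gamma)
        for kind in ("GD", "forward", "intermediate", "backward"):
            for tau in (1, 10, 500):
                res = ne_eq(fig1_state, ii, tau, kind)
                assert res.value == pytest.approx(fig1_state.NeE, rel=1e-9)

    def test_tau1_closed_forms(self, fig1_state, e1):
        # at tau=1 the equilibrium sizes reduce to rational functions of
        # NeE and II_inf(1)
        ii = make_ii_tau(fig1_state, e1)
        II1 = ii(1)
        NeE = fig1_state.NeE
        base = 1 / NeE + 2 * II1
        assert ne_eq(fig1_state, ii, 1, "forward").value == pytest.approx(1 / base, rel=1e-10)
        assert ne_eq(fig1_state, ii, 1, "intermediate").value == pytest.approx(
            (1 + II1 / 2) / base, rel=1e-10
        )
        assert ne_eq(fig1_state, ii, 1, "backward").value == pytest.approx(
            (1 + II1) / base, rel=1e-10
        )

    def test_backward_converges_to_NeE_for_long_intervals(self, fig1_state, e1):
        ii = make_ii_tau(fig1_state, e1)
        res = ne_eq(fig1_state, ii, 10**6, "backward")
        assert res.value == pytest.approx(fig1_state.NeE, rel=1e-3)

    def test_backward_monotone_in_tau(self, fig1_state, e1):
        ii = make_ii_tau(fig1_state, e1)
        taus = [1, 2, 5, 10, 50, 100, 500, 1000, 2000, 5000]
        vals = [ne_eq(fig1_state, ii, t, "backward").value for t in taus]
        assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))
        assert vals[-1] <= fig1_state.NeE * (1 + 1e-9)

    def test_gd_equals_NeE_for_any_weights(self, fig1_state, e1):
        ii = make_ii_tau(fig1_state, e1)
        for tau in (1, 7, 300):
            assert ne_eq(fig1_state, ii, tau, "GD").value == pytest.approx(
                fig1_state.NeE, rel=1e-10
            )


class TestWeightDominance:
    @pytest.mark.parametrize("s", [2, 3])
    def test_equal_weights_maximize_island_ne_v(self, s):
        # symmetric migration: the variance effective size over the weight
        # simplex (w = v) peaks at the reproductive (uniform) weights
        st = solve_equilibrium(make_island(s, 0.3, 30, 30))
        best = ne_eq(st, make_ii_tau(st, uniform_weights(s)), 5, "forward").value
        rng = np.random.default_rng(3)
        for _ in range(40):
            w = rng.dirichlet(np.ones(s))
            val = ne_eq(st, make_ii_tau(st, w), 5, "forward")
            if val.finite:
                assert val.value <= best * (1 + 1e-9)

    def test_split_weights_do_not_beat_equal_weights(self):
        # w given at both ends dominates using different end weights
        st = solve_equilibrium(make_island(3, 0.3, 30, 30))
        w = np.array([0.6, 0.3, 0.1])
        v = np.array([0.1, 0.3, 0.6])  # w@v < |w|^2
        same = ne_eq(st, make_ii_tau(st, w, w), 5, "forward").value
        split = ne_eq(st, make_ii_tau(st, w, v), 5, "forward").value
        assert split <= same * (1 + 1e-9)


class TestTauMax:
    def test_gd_and_backward_always_defined(self, fig1_state, e1):
        ii = make_ii_tau(fig1_state, e1)
        assert tau_max(fig1_state, ii, "GD") == math.inf
        assert tau_max(fig1_state, ii, "backward") == math.inf

    def test_reproductive_weights_never_fail(self, fig1_state):
        ii = make_ii_tau(fig1_state, fig1_state.gamma)
        assert tau_max(fig1_state, ii, "forward") == math.inf

    def test_existence_boundary_brackets_definition(self, fig1_state, e1):
        ii = make_ii_tau(fig1_state, e1)
        tm = tau_max(fig1_state, ii, "forward")
        assert ne_eq(fig1_state, ii, int(tm), "forward").status == "finite"
        assert ne_eq(fig1_state, ii, int(tm) + 1, "forward").status != "finite"


class TestIslandClosedForm:
    def test_full_weights_recover_NeE(self):
        s = 5
        st = solve_equilibrium(make_island(s, 0.4, 40, 40))
        for tau in (1, 10, 100):
            res = island_ne_v_eq(s, 0.4, 40, 40, k=s, l=s, tau=tau)
            assert res.value == pytest.approx(st.NeE, rel=1e-9)

    def test_panmixia_independent_of_overlap(self):
        s, Nc = 6, 30.0
        r0 = island_ne_v_eq(s, 1.0, Nc, Nc, k=1, l=0, tau=1)
        r1 = island_ne_v_eq(s, 1.0, Nc, Nc, k=1, l=1, tau=1)
        st = solve_equilibrium(make_island(s, 1.0, Nc, Nc))
        expected = 1 / (1 / st.NeE + 2 * (1 - 1 / s) / Nc)
        assert r0.value == pytest.approx(r1.value, rel=1e-12)
        assert r0.value == pytest.approx(expected, rel=1e-9)

    def test_local_weights_near_exact_value(self, fig1_state, e1):
        approx = island_ne_v_eq(10, 0.1, 50, 50, k=1, l=1, tau=1)
        exact = ne_eq(fig1_state, make_ii_tau(fig1_state, e1), 1, "forward")
        assert approx.value == pytest.approx(exact.value, rel=0.02)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            island_ne_v_eq(4, 0.2, 10, 10, k=2, l=3, tau=1)


def test_long_transient_gene_diversity_converges_to_NeE():
    # relative gene-diversity decline per generation approaches the
    # eigenvalue rate once the transient has died out
    from metapopne import build_A, founder_state, iterate, drift_term_I

    m = make_island(3, 0.2, 25, 25)
    st = solve_equilibrium(m)
    A = build_A(m)
    w = uniform_weights(3)
    T = int(20 * st.NeE)
    h_t = iterate(founder_state(m), A, T)
    h_t1 = iterate(h_t, A, 1)
    ne_gd = 1 / (2 * drift_term_I(h_t, h_t1, w))
    assert ne_gd == pytest.approx(st.NeE, rel=1e-3)
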