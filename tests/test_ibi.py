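"""Iterative Boltzmann inversion and the parametric soft pair potential."""

import numpy as np
import pytest
from scipy import integrate

from chromocg.dynamics import ForceField, LangevinParams, run_langevin
from chromocg.ibi import (
    CGPolymerSpec,
    IBIState,
    SoftPotentialParams,
    TabulatedPotential,
    _simulate_nonbonded_hist,
    alpha_of_r,
    fit_soft_potential,
    ibi_update,
    run_ibi,
    simulate_cg_with_soft_potential,
    soft_potential_eval,
    softness_and_depth,
    solve_attractive_phase,
    tabulate_soft_potential,
)


def _truth(V0=1.5, eps=0.3, r_m=1.0, r_c=1.8, eta1=2.0, eta2=2.0):
    mu, nu = solve_attractive_phase(r_m, r_c)
    return SoftPotentialParams(V0=V0, r_m=r_m, eps=eps, eta1=eta1, eta2=eta2,
                               mu=mu, nu=nu, r_c=r_c)


class TestUpdateRule:
    def test_fixed_point_leaves_potential_unchanged(self):
        r = np.linspace(0.05, 2.95, 30)
        pot = TabulatedPotential(r, np.sin(r) * 0.1, 3.0)
        p = np.exp(-r) / np.exp(-r).sum()
        state = IBIState(0, pot, p, p)
        new = ibi_update(state)
        # identical distributions: only the cutoff anchor (a constant shift
        # already equal to zero here) may act
        assert np.allclose(new.v, pot.v - pot.v[-1], atol=1e-14)

    def test_damping_prefactor_at_origin(self):
        assert alpha_of_r(0.0) == pytest.approx(0.2)

    def test_hand_computed_increment(self):
        # V = 0, P_i/P_target = e at r = 1 -> dV = 0.2 exp(-1/2)
        r = np.linspace(0.5, 2.0, 16)
        pot = TabulatedPotential(r, np.zeros(16), 2.1)
        q = np.full(16, 1.0 / 16)
        p = q.copy()
        k = np.argmin(np.abs(r - 1.0))
        p[k] = q[k] * np.e
        state = IBIState(0, pot, p, q)
        new = ibi_update(state)
        expected = 0.2 * np.exp(-r[k] ** 2 / 2)
        assert new.v[k] - new.v[-1] == pytest.approx(expected, rel=1e-6)

    def test_undersampled_bins_left_unchanged(self):
        r = np.linspace(0.05, 2.95, 30)
        pot = TabulatedPotential(r, np.zeros(30), 3.0)
        p = np.full(30, 1 / 30)
        q = np.full(30, 1 / 30)
        p[3] = 2 / 30
        counts = np.full(30, 100)
        counts[3] = 5  # below the 10-event floor
        state = IBIState(0, pot, p, q, counts=counts)
        new = ibi_update(state)
        assert new.v[3] == new.v[4] == 0.0


class TestAttractivePhase:
    def test_analytic_example(self):
        mu, nu = solve_attractive_phase(1.0, np.sqrt(3.0))
        assert mu == pytest.approx(np.pi / 2)
        assert nu == pytest.approx(np.pi / 2)
        assert np.cos(mu * 1.0 + nu) == pytest.approx(-1.0)

    def test_phase_identity(self):
        for r_m, r_c in [(0.5, 1.1), (1.0, 1.8), (2.0, 3.5)]:
            mu, _ = solve_attractive_phase(r_m, r_c)
            assert mu * (r_c**2 - r_m**2) == pytest.approx(np.pi)

    @pytest.mark.parametrize("r_m,r_c", [(0.8, 1.5), (1.0, 1.8), (1.5, 2.9)])
    def test_boundary_values_and_slopes(self, r_m, r_c):
        # value -eps at r_m, 0 at r_c; zero slope at both ends to 1e-8
        p = _truth(r_m=r_m, r_c=r_c)
        assert soft_potential_eval(p, r_m) == pytest.approx(-p.eps, abs=1e-12)
        h = 1e-6
        upper = soft_potential_eval(p, r_c - h)
        assert upper == pytest.approx(0.0, abs=1e-8)
        d_rm = (soft_potential_eval(p, r_m + h)
                - soft_potential_eval(p, r_m)) / h
        d_rc = (soft_potential_eval(p, r_c - h)
                - soft_potential_eval(p, r_c - 2 * h)) / h
        assert abs(d_rm) < 1e-4 and abs(d_rc) < 1e-4

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            solve_attractive_phase(2.0, 1.0)


class TestSoftPotentialEval:
    def test_value_at_origin(self):
        p = _truth(V0=3.0, eps=0.5)
        assert soft_potential_eval(p, 0.0) == pytest.approx(3.0 - 0.5)

    def test_depth_attained_at_minimum(self):
        p = _truth(eps=0.7)
        assert soft_potential_eval(p, p.r_m) == pytest.approx(-0.7)

    def test_zero_beyond_cutoff(self):
        p = _truth()
        assert soft_potential_eval(p, p.r_c) == 0.0
        assert soft_potential_eval(p, 10.0) == 0.0


class TestSoftPotentialFit:
    def test_round_trip_parameter_recovery(self):
        p = _truth(V0=3.0, eps=0.5, eta1=2.5, eta2=1.8)
        tab = tabulate_soft_potential(p, dr=0.01)
        fit, rms = fit_soft_potential(tab)
        assert fit.r_m == pytest.approx(p.r_m, rel=0.01)
        assert fit.eps == pytest.approx(p.eps, rel=0.01)
        assert fit.r_c == pytest.approx(p.r_c, rel=0.01)
        assert fit.V0 == pytest.approx(p.V0, rel=0.05)
        assert fit.eta1 == pytest.approx(p.eta1, rel=0.05)
        assert fit.eta2 == pytest.approx(p.eta2, rel=0.05)
        # sup-norm of the re-tabulated fit
        r = tab.r
        assert np.abs(soft_potential_eval(fit, r) - tab.v).max() < 0.05

    def test_purely_repulsive_table_degenerates(self):
        r = np.linspace(0.0, 2.0, 100)
        v = np.maximum(1.0 - r, 0.0) ** 2
        fit, _ = fit_soft_potential(TabulatedPotential(r, v, 2.0))
        assert fit.eps == 0.0
        assert fit.r_c == pytest.approx(1.0, abs=0.03)

    def test_noisy_table_recovery_within_ten_percent(self, rng):
        p = _truth(V0=3.0, eps=0.5)
        tab = tabulate_soft_potential(p, dr=0.02)
        noisy = TabulatedPotential(
            tab.r, tab.v + rng.normal(0, 0.05, tab.v.size), tab.cutoff
        )
        fit, rms = fit_soft_potential(noisy)
        assert fit.V0 == pytest.approx(p.V0, rel=0.1)
        assert fit.r_m == pytest.approx(p.r_m, rel=0.1)
        assert rms > 0


class TestSoftnessAndDepth:
    def test_harmonic_like_repulsion(self):
        r = np.linspace(0.0, 2.0, 201)
        v = np.where(r < 1.0, (r - 1.0) ** 2, 0.0)
        softness, eps = softness_and_depth(TabulatedPotential(r, v, 2.0))
        assert softness == pytest.approx(0.5, rel=0.05)
        assert eps == 0.0

    def test_scaling_potential_halves_softness(self):
        p1 = _truth(V0=2.0, eps=0.0001)
        p2 = _truth(V0=4.0, eps=0.0002)
        s1, _ = softness_and_depth(p1)
        s2, _ = softness_and_depth(p2)
        assert s2 == pytest.approx(s1 / 2, rel=1e-3)

    def test_depth_does_not_alter_softness(self):
        s1, e1 = softness_and_depth(_truth(V0=3.0, eps=0.2))
        s2, e2 = softness_and_depth(_truth(V0=3.0, eps=0.8))
        assert s1 == pytest.approx(s2, rel=1e-6)
        assert (e1, e2) == (0.2, 0.8)


class TestCGSimulation:
    def test_bond_statistics_without_pair_term(self):
        # harmonic-bond Boltzmann statistics against the exact radial moments
        k, r0 = 50.0, 1.0
        spec = CGPolymerSpec(n_cg=40, l_cg=r0, k_cg=k, nonbonded=None)
        ens = simulate_cg_with_soft_potential(spec, 50, seed=3, n_steps=4000)
        bl = np.linalg.norm(np.diff(ens.coords, axis=1), axis=2).ravel()
        f = lambda r: r**2 * np.exp(-0.5 * k * (r - r0) ** 2)
        z = integrate.quad(f, 0, 5)[0]
        m1 = integrate.quad(lambda r: r * f(r), 0, 5)[0] / z
        m2 = integrate.quad(lambda r: r * r * f(r), 0, 5)[0] / z
        assert bl.mean() == pytest.approx(m1, rel=0.01)
        assert bl.var() == pytest.approx(m2 - m1**2, rel=0.05)

    def test_two_body_boltzmann_distribution(self):
        # two beads, soft pair + weak harmonic tether (k_w r^2 / 2 with
        # k_w = 1), long single trajectory; the sampled separation follows
        # P(r) ~ r^2 exp(-V_soft(r) - k_w r^2 / 2) exactly
        p = _truth(V0=2.0, eps=0.5)
        tab = tabulate_soft_potential(p)
        kw = 1.0
        ff = ForceField(chain_k=kw, chain_r0=1e-9, pair=tab)
        x = np.array([[0.0, 0, 0], [1.2, 0, 0]])
        tr = run_langevin(
            x, ff, LangevinParams(n_steps=5_000_000, sample_every=50, seed=2)
        )
        r = np.linalg.norm(tr.production[:, 1] - tr.production[:, 0], axis=1)
        edges = np.arange(0, 3.0, 0.1)
        h, _ = np.histogram(r, bins=edges, density=True)
        cent = 0.5 * (edges[:-1] + edges[1:])
        ref = cent**2 * np.exp(-soft_potential_eval(p, cent)
                               - 0.5 * kw * cent**2)
        ref /= ref.sum() * 0.1
        sel = ref > 0.1 * ref.max()
        assert np.abs((h[sel] - ref[sel]) / ref[sel]).max() < 0.05

    def test_same_seed_identical_ensemble(self):
        spec = CGPolymerSpec(n_cg=20, l_cg=1.0, k_cg=30.0)
        a = simulate_cg_with_soft_potential(spec, 5, seed=9, n_steps=500)
        b = simulate_cg_with_soft_potential(spec, 5, seed=9, n_steps=500)
        assert np.array_equal(a.coords, b.coords)


class TestRunIBI:
    def test_self_target_converges_immediately(self):
        # target measured from the zero-potential chain itself: the flat
        # start is already the fixed point, so iteration 0 converges
        spec = CGPolymerSpec(n_cg=50, l_cg=1.0, k_cg=50.0)
        edges = np.arange(0.0, 3.05, 0.1)
        dens, _ = _simulate_nonbonded_hist(spec, None, edges, seed=5,
                                           n_replicas=24, n_steps=5000)
        pot, hist = run_ibi(dens, edges, spec, max_iter=5, kl_tol=0.01,
                            seed=6, n_replicas=24, n_steps=5000)
        assert len(hist) == 1
        assert hist[-1].kl_history[0] < 0.01
        assert np.allclose(pot.v, 0.0)

    def test_running_minimum_kl_non_increasing(self):
        spec = CGPolymerSpec(n_cg=30, l_cg=1.0, k_cg=50.0)
        truth = _truth()
        edges = np.arange(0.0, 3.05, 0.1)
        dens, _ = _simulate_nonbonded_hist(
            spec, tabulate_soft_potential(truth), edges, seed=1,
            n_replicas=8, n_steps=2000,
        )
        _, hist = run_ibi(dens, edges, spec, max_iter=5, kl_tol=1e-6, seed=2,
                          n_replicas=8, n_steps=2000)
        kl = hist[-1].kl_history
        running = np.minimum.accumulate(kl)
        assert np.all(np.diff(running) <= 0)

    def test_recovers_known_soft_potential(self):
        # the oracle experiment: generate the target from a known soft
        # potential on a 50-bead CG chain, invert from a flat start.
        # KL(target || iterate) drops below 0.05 within 30 iterations, and
        # the tabulated potential converges onto the truth over the repulsive
        # shoulder and well, [0.5 r_m, r_c]
        truth = _truth(V0=1.5, eps=0.3)
        spec = CGPolymerSpec(n_cg=50, l_cg=1.0, k_cg=50.0)
        edges = np.arange(0.0, 3.05, 0.1)
        dens_t, _ = _simulate_nonbonded_hist(
            spec, tabulate_soft_potential(truth), edges, seed=777,
            n_replicas=24, n_steps=5000,
        )
        pot, hist = run_ibi(dens_t, edges, spec, max_iter=60, kl_tol=1e-5,
                            seed=1, n_replicas=16, n_steps=4000)
        kl = hist[-1].kl_history
        assert min(kl[:30]) < 0.05
        r = pot.r
        m = (r >= 0.5 * truth.r_m) & (r <= truth.r_c)
        err = np.abs(pot.v[m] - soft_potential_eval(truth, r[m]))
        assert err.max() < 0.2
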