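"""Coarse-grained observables: geometry, distributions, potentials, fits."""

import numpy as np
import pytest
from scipy import stats

from chromocg.coarse_grain import (
    AngleDeconvolution,
    CGSpec,
    EffectivePotential,
    angle_dihedral_energy_map,
    angle_distribution,
    cg_bond_angles,
    cg_bond_lengths,
    cg_dihedrals,
    cg_summary,
    cg_trace,
    deconvolute_two_gaussians,
    effective_potential,
    fit_bending_stiffness,
    nonbonded_overlap_fraction,
    overlap_parameter,
    radius_of_gyration,
    rg_profile,
    spring_constant,
)
from chromocg.dynamics import Ensemble
from chromocg.synthetic import sample_ideal_chain


class TestRadiusOfGyration:
    def test_single_point_is_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_points_half_distance(self):
        x = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert radius_of_gyration(x) == pytest.approx(1.5)

    def test_unit_square_corners(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        assert radius_of_gyration(x) == pytest.approx(1 / np.sqrt(2))


class TestCGTrace:
    def test_nb_one_is_identity(self, rng):
        x = rng.normal(size=(12, 3))
        assert np.array_equal(cg_trace(x, 1), x)

    def test_nb_equals_n_gives_single_centroid(self, rng):
        x = rng.normal(size=(9, 3))
        tr = cg_trace(x, 9)
        assert tr.shape == (1, 3)
        assert np.allclose(tr[0], x.mean(axis=0))

    def test_collinear_blocks_give_midpoints(self):
        x = np.column_stack([np.arange(6, dtype=float), np.zeros(6),
                             np.zeros(6)])
        tr = cg_trace(x, 2)
        assert np.allclose(tr[:, 0], [0.5, 2.5, 4.5])

    def test_sliding_windows_are_running_means(self, rng):
        x = rng.normal(size=(10, 3))
        tr = cg_trace(x, CGSpec(4, "sliding"))
        assert tr.shape == (7, 3)
        assert np.allclose(tr[2], x[2:6].mean(axis=0))

    def test_remainder_dropped_with_warning(self, rng, caplog):
        x = rng.normal(size=(11, 3))
        with caplog.at_level("WARNING"):
            tr = cg_trace(x, 4)
        assert tr.shape == (2, 3)

    def test_chain_shorter_than_window_rejected(self, rng):
        with pytest.raises(ValueError):
            cg_trace(rng.normal(size=(3, 3)), 5)


class TestVarianceDecomposition:
    @pytest.mark.parametrize("nb", [2, 5, 10])
    def test_chain_rg_splits_into_trace_and_block_parts(self, rng, nb):
        # Rg^2(chain) = Rg^2(CG trace) + mean within-block Rg^2, exactly;
        # the CG trace is therefore always more compact than the chain
        x = rng.normal(size=(60, 3)) * 2.0
        lhs = radius_of_gyration(x) ** 2
        tr = cg_trace(x, nb)
        blocks = x.reshape(-1, nb, 3)
        c = blocks - blocks.mean(axis=1, keepdims=True)
        within = (c**2).sum(axis=2).mean(axis=1)
        rhs = radius_of_gyration(tr) ** 2 + within.mean()
        assert lhs == pytest.approx(rhs, abs=1e-10)
        assert radius_of_gyration(tr) < radius_of_gyration(x)


class TestBondsAnglesDihedrals:
    def test_bond_length_simple_distance(self):
        tr = np.array([[0.0, 0, 0], [0, 0, 3.0]])
        assert cg_bond_lengths(tr)[0] == pytest.approx(3.0)

    def test_straight_chain_bond_scales_with_block_size(self):
        x = np.column_stack([np.arange(12, dtype=float), np.zeros(12),
                             np.zeros(12)])
        lcg = cg_bond_lengths(cg_trace(x, 3))
        assert np.allclose(lcg, 3.0)

    @pytest.mark.parametrize("pts,expected", [
        ([[0, 0, 0], [1, 0, 0], [2, 0, 0]], 180.0),  # collinear forward
        ([[0, 0, 0], [1, 0, 0], [1, 1, 0]], 90.0),  # right-angle bend
        ([[0, 0, 0], [1, 0, 0], [0, 0, 0]], 0.0),  # complete fold-back
    ])
    def test_bond_angle_conventions(self, pts, expected):
        th = cg_bond_angles(np.asarray(pts, float))
        assert th[0] == pytest.approx(expected, abs=1e-9)

    def test_zero_length_bond_excluded(self, caplog):
        tr = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with caplog.at_level("WARNING"):
            th = cg_bond_angles(tr)
        assert len(th) == 1  # only the angle not touching the null bond

    @pytest.mark.parametrize("pts,expected", [
        # planar trans zigzag
        ([[0, 0, 0], [1, 1, 0], [2, 0, 0], [3, 1, 0]], 180.0),
        # planar cis (1 and 4 on the same side)
        ([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], 0.0),
        # right-handed quarter twist
        ([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1]], 90.0),
    ])
    def test_dihedral_conventions(self, pts, expected):
        phi = cg_dihedrals(np.asarray(pts, float))
        assert phi[0] == pytest.approx(expected, abs=1e-9)

    def test_collinear_triple_excluded(self):
        tr = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0],
                       [4, 1, 1]], float)
        phi = cg_dihedrals(tr)
        assert len(phi) == 1


class TestOverlapAndSpring:
    def test_overlap_boundary_value(self):
        assert overlap_parameter(0.5, 1.0) == pytest.approx(1.0)

    def test_overlap_requires_positive_bond(self):
        with pytest.raises(ValueError):
            overlap_parameter(1.0, 0.0)

    def test_two_value_sample_hand_calculation(self):
        assert spring_constant(np.array([1.0, 3.0])) == pytest.approx(1.0)

    def test_gaussian_sample_recovers_variance(self, rng):
        lengths = rng.normal(2.0, 0.5, size=10_000)
        assert spring_constant(lengths) == pytest.approx(4.0, rel=0.05)

    def test_rigid_bond_rejected(self):
        with pytest.raises(ValueError, match="rigid"):
            spring_constant(np.full(10, 2.0))


class TestAngleDistribution:
    def test_ideal_chain_sine_measure_is_uniform(self):
        ens = sample_ideal_chain(3, 10_000, seed=8)
        th = np.concatenate([cg_bond_angles(c) for c in ens.coords])
        counts, edges = np.histogram(th, bins=36, range=(0, 180))
        # expected counts under P(theta) = sin(theta)/2
        exp = (np.cos(np.radians(edges[:-1])) - np.cos(np.radians(edges[1:])))
        exp = exp / exp.sum() * counts.sum()
        assert stats.chisquare(counts, exp).pvalue > 0.01

    def test_point_mass_occupies_single_bin(self):
        ad = angle_distribution(np.full(500, 90.0))
        assert (ad.p > 0).sum() == 1

    def test_sin_correction_inverts(self, rng):
        th = np.degrees(np.arccos(rng.uniform(-1, 1, size=20_000)))
        ad = angle_distribution(th)
        occ = np.isfinite(ad.p_tilde)
        back = ad.p_tilde[occ] * np.sin(np.radians(ad.centers[occ]))
        back /= back.sum() * 5.0
        p = ad.p[occ] / (ad.p[occ].sum() * 5.0)
        assert np.allclose(back, p, atol=1e-12)

    def test_outermost_bins_masked(self, rng):
        ad = angle_distribution(rng.uniform(0, 180, 1000))
        assert np.isnan(ad.p_tilde[0]) and np.isnan(ad.p_tilde[-1])

    def test_coarse_graining_shifts_ideal_chain_angles_up(self):
        # block-averaging straightens the trace: mean theta grows with n_b
        ens = sample_ideal_chain(100, 400, seed=12)
        s1 = cg_summary(ens, 1)
        s5 = cg_summary(ens, 5)
        assert s5.theta_deg.mean() > s1.theta_deg.mean()


class TestEffectivePotential:
    def test_uniform_density_flat_potential(self):
        ep = effective_potential(np.linspace(0, 1, 11), np.full(11, 0.5))
        assert np.allclose(ep.v, 0.0)

    def test_gaussian_density_quadratic_curvature(self):
        g = np.linspace(-3, 3, 121)
        sd = 0.5
        dens = np.exp(-0.5 * (g / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        ep = effective_potential(g, dens)
        curv = 2 * np.polyfit(g, ep.v, 2)[0]
        assert curv == pytest.approx(1 / sd**2, rel=0.02)

    def test_two_bin_density_log_ratio(self):
        ep = effective_potential(np.array([0.0, 1.0]), np.array([0.8, 0.2]))
        assert ep.v[1] - ep.v[0] == pytest.approx(np.log(4.0))

    def test_empty_bins_masked_not_extrapolated(self):
        ep = effective_potential(np.arange(4.0), np.array([0.5, 0.0, 0.3, 0.2]))
        assert np.isnan(ep.v[1])

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            effective_potential(np.arange(3.0), np.zeros(3))


class TestDeconvolution:
    def test_recovers_two_population_mixture(self, rng):
        draw = np.where(
            rng.uniform(size=10_000) < 0.5,
            rng.normal(60, 10, 10_000),
            rng.normal(110, 25, 10_000),
        )
        ad = angle_distribution(draw[(draw >= 0) & (draw <= 180)])
        dec = deconvolute_two_gaussians(ad.centers, ad.p)
        assert dec.mean1 == pytest.approx(60, abs=3)
        assert dec.mean2 == pytest.approx(110, abs=3)
        assert dec.sd2 / dec.sd1 == pytest.approx(2.5, rel=0.2)

    def test_single_gaussian_degenerates(self, rng):
        draw = rng.normal(90, 15, 10_000)
        ad = angle_distribution(draw)
        dec = deconvolute_two_gaussians(ad.centers, ad.p)
        assert dec.weight1 > 0.9 or dec.weight2 > 0.9 \
            or abs(dec.mean1 - dec.mean2) < 5

    def test_flat_input_flagged_poor_fit(self):
        grid = np.linspace(2.5, 177.5, 36)
        dec = deconvolute_two_gaussians(grid, np.full(36, 1 / 180))
        assert not dec.ok
        assert dec.residual > AngleDeconvolution.POOR_FIT_THRESHOLD


class TestStiffnessFit:
    def test_exact_cosine_form_recovered(self):
        th = np.linspace(0, 180, 73)
        v = 0.5 * 1.0 * (1 + np.cos(np.radians(th) - np.radians(60)))
        fit = fit_bending_stiffness(EffectivePotential("theta", th, v))
        assert fit.k_b == pytest.approx(1.0, rel=0.01)
        assert fit.theta0 == pytest.approx(60.0, abs=0.5)

    def test_flat_potential_gives_zero_stiffness(self):
        th = np.linspace(0, 180, 37)
        fit = fit_bending_stiffness(EffectivePotential("theta", th,
                                                       np.zeros(37)))
        assert fit.k_b == pytest.approx(0.0, abs=1e-3)

    def test_ideal_chain_is_floppy(self):
        # flat sine-corrected density -> bending stiffness well below 0.1 kBT
        # (enough samples that edge-bin noise in P~ cannot mimic stiffness)
        ens = sample_ideal_chain(3, 100_000, seed=2)
        th = np.concatenate([cg_bond_angles(c) for c in ens.coords])
        ad = angle_distribution(th)
        occ = np.isfinite(ad.p_tilde)
        ep = effective_potential(ad.centers[occ], ad.p_tilde[occ], "theta")
        fit = fit_bending_stiffness(ep)
        assert fit.k_b < 0.1


class TestEnergyMap:
    def test_flat_factors_give_flat_map(self):
        vt = EffectivePotential("theta", np.arange(5.0), np.zeros(5))
        vp = EffectivePotential("phi", np.arange(7.0), np.zeros(7))
        assert np.allclose(angle_dihedral_energy_map(vt, vp), 0.0)

    def test_constant_along_flat_axis(self):
        vt = EffectivePotential("theta", np.arange(5.0),
                                np.arange(5.0) ** 2 / 4)
        vp = EffectivePotential("phi", np.arange(7.0), np.zeros(7))
        m = angle_dihedral_energy_map(vt, vp)
        assert np.allclose(m, m[:, :1])

    def test_minimum_at_marginal_minima(self, rng):
        vt = EffectivePotential("theta", np.arange(6.0),
                                rng.uniform(0, 2, 6))
        vp = EffectivePotential("phi", np.arange(8.0), rng.uniform(0, 2, 8))
        m = angle_dihedral_energy_map(vt, vp)
        kt, kp = np.unravel_index(np.nanargmin(m), m.shape)
        assert kt == np.argmin(vt.v) and kp == np.argmin(vp.v)


class TestNonbondedOverlap:
    def test_stretched_chain_never_overlaps(self):
        x = np.column_stack([np.arange(40, dtype=float) * 5, np.zeros(40),
                             np.zeros(40)])
        ens = Ensemble(coords=x[None])
        _, agg = nonbonded_overlap_fraction(ens, 4, l_cg_ref=1.0)
        assert agg == 0.0

    def test_coincident_centers_always_overlap(self):
        x = np.zeros((40, 3))
        x += np.arange(40)[:, None] * 1e-6  # distinct but tiny
        ens = Ensemble(coords=x[None])
        _, agg = nonbonded_overlap_fraction(ens, 4, l_cg_ref=1.0)
        assert agg == 1.0

    def test_matches_brute_force(self, rng):
        coords = rng.normal(size=(50, 24, 3)) * 2
        ens = Ensemble(coords=coords)
        per_pair, agg = nonbonded_overlap_fraction(ens, 4, l_cg_ref=2.0)
        centers = coords.reshape(50, 6, 4, 3).mean(axis=2)
        events = []
        for s in range(50):
            for i in range(6):
                for j in range(6):
                    if abs(i - j) >= 2:
                        events.append(
                            np.linalg.norm(centers[s, i] - centers[s, j]) < 2.0
                        )
        assert agg == pytest.approx(np.mean(events))


class TestProfiles:
    def test_identical_conformations_have_zero_sd(self, rng):
        x = rng.normal(size=(30, 3))
        ens = Ensemble(coords=np.repeat(x[None], 5, axis=0))
        prof = rg_profile(ens, 5)
        assert np.allclose(prof["sd"], 0.0)

    def test_saw_profile_is_flat_along_contour(self, small_saw_ensemble):
        prof = rg_profile(small_saw_ensemble, 10)
        m = prof["mean"].to_numpy()
        # homogeneous chain: variation along the contour stays within 15%
        assert m.std() / m.mean() < 0.15
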