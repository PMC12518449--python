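import numpy as np
import pytest

import peaklag as pk
from peaklag import eigen


def constant_potential(g):
    return lambda x: np.full_like(np.asarray(x, dtype=float), g)


class TestDirichletSolver:
    def test_constant_potential_closed_form(self):
        # lambda = eps^2 * (pi/(2R))^2 - g, eigenvector ~ cos(pi x / (2R))
        g, eps, radius = 1.0, 0.2, 5.0
        spec = eigen.EigenProblemSpec(constant_potential(g), eps, radius,
                                      center=0.0, dx=0.01)
        pair = eigen.principal_eigenpair_dirichlet(spec)
        exact = eps**2 * (np.pi / (2 * radius)) ** 2 - g
        assert pair.eigenvalue == pytest.approx(exact, abs=1e-7)
        sup = pair.to_sup_one()
        cos = np.cos(np.pi * sup.nodes / (2 * radius))
        assert np.abs(sup.eigenvector - cos).max() < 1e-4

    def test_potential_shift_identity(self):
        spec1 = eigen.EigenProblemSpec(constant_potential(1.0), 0.1, 5.0,
                                       center=0.0, dx=0.01)
        spec2 = eigen.EigenProblemSpec(constant_potential(1.7), 0.1, 5.0,
                                       center=0.0, dx=0.01)
        p1 = eigen.principal_eigenpair_dirichlet(spec1)
        p2 = eigen.principal_eigenpair_dirichlet(spec2)
        assert p2.eigenvalue == pytest.approx(p1.eigenvalue - 0.7, abs=1e-12)
        assert p2.eigenvector == pytest.approx(p1.eigenvector, rel=1e-9)

    def test_fig4_quadratic_peak_bracket(self, single_peak):
        # Rayleigh lower bound plus harmonic upper estimate
        pair = eigen.principal_eigenpair_drift(single_peak.frozen, 1.0, 0.1, 30.0)
        assert -1.75 < pair.eigenvalue < -1.55

    def test_eigenvector_positive_and_l1(self, single_peak):
        spec = eigen.EigenProblemSpec(
            lambda x: np.asarray(single_peak.frozen(x)) - 0.25, 0.1, 20.0)
        pair = eigen.principal_eigenpair_dirichlet(spec)
        assert pair.eigenvector.min() >= 0.0
        assert pair.eigenvector.max() > 0.0
        assert pair.dx * pair.eigenvector.sum() == pytest.approx(1.0)

    def test_drift_spec_rejected(self):
        spec = eigen.EigenProblemSpec(constant_potential(1.0), 0.1, 5.0,
                                      center=0.0, drift=1.0)
        with pytest.raises(ValueError):
            eigen.principal_eigenpair_dirichlet(spec)


class TestDriftProblem:
    def test_similarity_eigenvalue_equals_symmetric(self, single_peak):
        c, eps = 1.0, 0.1
        sym_spec = eigen.EigenProblemSpec(
            lambda x: np.asarray(single_peak.frozen(x)) - c**2 / 4, eps, 20.0)
        sym = eigen.principal_eigenpair_dirichlet(sym_spec)
        drift = eigen.principal_eigenpair_drift(single_peak.frozen, c, eps, 20.0)
        assert drift.eigenvalue == sym.eigenvalue  # identical by construction

    def test_direct_agrees_with_similarity(self, single_peak):
        c, eps = 1.0, 0.1
        sim = eigen.principal_eigenpair_drift(single_peak.frozen, c, eps, 10.0,
                                              dx=0.01)
        direct = eigen.principal_eigenpair_drift(single_peak.frozen, c, eps,
                                                 10.0, dx=0.01, method="direct")
        assert abs(sim.eigenvalue - direct.eigenvalue) < 1e-3

    def test_zero_drift_reduces_to_dirichlet(self, single_peak):
        pair0 = eigen.principal_eigenpair_drift(single_peak.frozen, 0.0, 0.1,
                                                20.0)
        spec = eigen.EigenProblemSpec(
            lambda x: np.asarray(single_peak.frozen(x)), 0.1, 20.0)
        sym = eigen.principal_eigenpair_dirichlet(spec)
        assert pair0.eigenvalue == pytest.approx(sym.eigenvalue, abs=1e-14)

    def test_eigenvector_concentrates_at_lagged_optimum(self, single_peak):
        pair = eigen.principal_eigenpair_drift(single_peak.frozen, 1.0, 0.1,
                                               20.0)
        argmax = pair.nodes[np.argmax(pair.eigenvector)]
        assert abs(argmax - 39.5) <= 2 * pair.dx

    def test_orientation_invariance(self, single_peak):
        # x -> -x with c -> -c leaves the eigenvalue unchanged
        c, eps = 1.0, 0.1

        def mirrored(x):
            return np.asarray(single_peak.frozen(-np.asarray(x)))

        lam = eigen.principal_eigenpair_drift(single_peak.frozen, c, eps, 15.0,
                                              center=40.0).eigenvalue
        lam_m = eigen.principal_eigenpair_drift(mirrored, -c, eps, 15.0,
                                                center=-40.0).eigenvalue
        assert lam_m == pytest.approx(lam, abs=1e-12)


class TestLambdaRCurve:
    def test_constant_potential_closed_form_decreasing(self):
        g, eps = 1.0, 0.2
        spec = eigen.EigenProblemSpec(constant_potential(g), eps, 5.0,
                                      center=0.0, dx=0.005)
        curve = eigen.lambda_R_curve(spec, [2.5, 5.0, 10.0])
        for r, lam in curve:
            exact = eps**2 * (np.pi / (2 * r)) ** 2 - g
            assert lam == pytest.approx(exact, abs=1e-5)
        lams = [lam for _, lam in curve]
        assert lams[0] > lams[1] > lams[2]

    def test_fig4_peak_stabilizes(self, single_peak):
        spec = eigen.EigenProblemSpec(
            lambda x: np.asarray(single_peak.frozen(x)) - 0.25, 0.1, 40.0,
            center=40.0, dx=0.005)
        curve = eigen.lambda_R_curve(spec, [5.0, 10.0, 20.0, 40.0])
        lams = [lam for _, lam in curve]
        assert all(l2 <= l1 + 1e-10 for l1, l2 in zip(lams, lams[1:]))
        assert abs(lams[-1] - lams[-2]) < 1e-8

    def test_rayleigh_lower_bound(self, single_peak):
        spec = eigen.EigenProblemSpec(
            lambda x: np.asarray(single_peak.frozen(x)) - 0.25, 0.1, 40.0,
            center=40.0, dx=0.005)
        vmax = 1.75  # max of the potential
        for _, lam in eigen.lambda_R_curve(spec, [5.0, 10.0, 20.0]):
            assert lam >= -vmax

    def test_non_increasing_radii_rejected(self, single_peak):
        spec = eigen.EigenProblemSpec(
            lambda x: np.asarray(single_peak.frozen(x)), 0.1, 40.0)
        with pytest.raises(ValueError):
            eigen.lambda_R_curve(spec, [10.0, 5.0])


class TestEpsilonLimit:
    def test_quadratic_peak_harmonic_gaps(self, single_peak):
        rep = eigen.epsilon_limit_check(single_peak, 1.0, [0.2, 0.1, 0.05], 20.0)
        assert rep.limit == pytest.approx(-1.75)
        assert rep.gaps_positive and rep.gaps_decreasing
        for eps, _, gap in rep.rows:
            # harmonic asymptotic eps*sqrt(|a''|/2) = eps for |a''| = 2
            assert gap == pytest.approx(eps, rel=0.25)
        assert rep.harmonic_bound_met
        assert not rep.extinction_branch

    def test_gap_invariant_under_drift_shift(self, single_peak):
        # the c-transformed potential differs by the constant c^2/4 only
        lam0 = eigen.principal_eigenpair_drift(single_peak.frozen, 0.0, 0.1,
                                               20.0).eigenvalue
        lam1 = eigen.principal_eigenpair_drift(single_peak.frozen, 1.0, 0.1,
                                               20.0).eigenvalue
        assert lam1 - lam0 == pytest.approx(0.25, abs=1e-12)

    def test_extinction_branch_flagged(self, single_peak):
        rep = eigen.epsilon_limit_check(single_peak, 4.0, [0.2, 0.1], 20.0)
        assert rep.extinction_branch
        assert all(lam > 0 for _, lam, _ in rep.rows)


class TestDecayEnvelope:
    def test_fig4_peak_no_violations(self, single_peak):
        pair = eigen.principal_eigenpair_drift(single_peak.frozen, 1.0, 0.1,
                                               20.0)
        rep = eigen.decay_envelope_check(pair, single_peak, 1.0, 0.1)
        assert rep.violations == 0

    def test_envelope_constants_as_printed(self, single_peak):
        pair = eigen.principal_eigenpair_drift(single_peak.frozen, 1.0, 0.1,
                                               20.0)
        rep = eigen.decay_envelope_check(pair, single_peak, 1.0, 0.1)
        a_max, c, lam = 2.0, 1.0, pair.eigenvalue
        assert rep.kappa_upper == pytest.approx((np.sqrt(a_max) + c) / 2)
        assert rep.kappa_lower == pytest.approx(
            c / 2 + 2 * np.sqrt(abs(-0.5 + lam - c**2 / 4)))

    def test_zero_drift_symmetric_envelopes(self, single_peak):
        pair = eigen.principal_eigenpair_drift(single_peak.frozen, 0.0, 0.1,
                                               20.0)
        rep = eigen.decay_envelope_check(pair, single_peak, 0.0, 0.1)
        assert rep.kappa_upper == pytest.approx(np.sqrt(2.0) / 2)
        assert rep.violations == 0


class TestPersistenceClassification:
    def test_fig6_style_dominant_one(self):
        a1 = pk.make_bump(32.0, 1.75, 2, -1.0)
        a2 = pk.make_bump(48.0, 2.5, 2, 2.5)
        rep = eigen.persistence_classification(a1, a2, -1.0, 2.5, 0.5, 0.05,
                                               10.0)
        assert rep.lagged_fitnesses == pytest.approx((1.0, 0.4375))
        assert rep.verdict == "persists"
        assert rep.dominant_index == 1

    def test_slow_second_peak_dominant_two(self):
        a1 = pk.make_bump(32.0, 1.75, 2, -1.0)
        a2 = pk.make_bump(48.0, 2.5, 2, 1.0)
        rep = eigen.persistence_classification(a1, a2, -1.0, 1.0, 0.5, 0.05,
                                               10.0)
        assert rep.lagged_fitnesses[1] == pytest.approx(1.75)
        assert rep.dominant_index == 2

    def test_both_overrun_extinct(self):
        a1 = pk.make_bump(32.0, 1.75, 2, -4.0)
        a2 = pk.make_bump(48.0, 2.5, 2, 4.0)
        rep = eigen.persistence_classification(a1, a2, -4.0, 4.0, 0.5, 0.05,
                                               10.0)
        assert rep.verdict == "extinct"
        assert min(rep.lambda1, rep.lambda2) >= 0

    def test_crossover_at_c2_equals_two(self):
        # heights 7/4 and 5/2, c1 = -1: closed-form crossover c2^2 = 4
        a1 = pk.make_bump(32.0, 1.75, 2, -1.0)
        doms = []
        for c2 in (1.0, 1.5, 2.0, 2.5):
            a2 = pk.make_bump(48.0, 2.5, 2, c2)
            rep = eigen.persistence_classification(a1, a2, -1.0, c2, 0.5,
                                                   0.05, 10.0)
            doms.append(rep.dominant_index)
        assert doms[0] == doms[1] == 2
        assert doms[3] == 1
        assert doms[2] in (None, 1, 2)  # exact tie at the crossover

    def test_wrong_speed_signs_warn(self):
        a1 = pk.make_bump(32.0, 1.75, 2, 1.0)
        a2 = pk.make_bump(48.0, 2.5, 2, 2.0)
        with pytest.warns(UserWarning, match="c1 < 0 < c2"):
            eigen.persistence_classification(a1, a2, 1.0, 2.0, 0.5, 0.1, 10.0)


class TestInvariants:
    def test_mass_identity(self, single_peak):
        pair = eigen.principal_eigenpair_drift(single_peak.frozen, 1.0, 0.1,
                                               20.0)
        integral = eigen.mass_identity(single_peak.frozen, pair)
        assert abs(integral - (-pair.eigenvalue)) < 1e-3

    def test_rayleigh_quotient_bounds_eigenvalue(self, single_peak):
        eps = 0.1
        spec = eigen.EigenProblemSpec(
            lambda x: np.asarray(single_peak.frozen(x)) - 0.25, eps, 20.0)
        pair = eigen.principal_eigenpair_dirichlet(spec)
        nodes, dx = spec.interior_nodes()
        v = np.asarray(spec.potential(nodes))
        rng = np.random.default_rng(5)
        for _ in range(10):
            phi = rng.uniform(0.01, 1.0, len(nodes))
            grad = np.diff(np.concatenate([[0.0], phi, [0.0]])) / dx
            quotient = ((eps**2 * np.sum(grad**2) - np.sum(v * phi**2) * 1.0)
                        / np.sum(phi**2))
            assert quotient >= pair.eigenvalue - 1e-10

    def test_normalization_independence(self, single_peak):
        pair = eigen.principal_eigenpair_drift(single_peak.frozen, 1.0, 0.1,
                                               20.0)
        assert pair.to_sup_one().eigenvalue == pair.to_l1_one().eigenvalue
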