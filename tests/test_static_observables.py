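"""Sizes, shapes, contour correlations, contacts and scaling fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringmelt.fcc_lattice import A
from ringmelt.fixtures import generate_fixture
from ringmelt.static_observables import (
    bond_correlation,
    contact_probability,
    double_fold_reference,
    fit_scaling,
    gyration_radius_sq,
    gyration_tensor,
    magnetic_radius_sq,
    oriented_area,
    zeta_transform,
)


class TestGyration:
    def test_coincident_points_have_zero_radius(self):
        assert gyration_radius_sq(np.zeros((5, 3))) == 0.0

    def test_square_of_side_s(self):
        s = 2.0
        sq = np.array([[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0]]) * A
        assert gyration_radius_sq(sq) == pytest.approx(s ** 2 / 2.0)

    @given(st.integers(min_value=4, max_value=40), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_trace_identity(self, n, seed):
        r = np.random.default_rng(seed).normal(size=(n, 3))
        assert gyration_tensor(r).sum() == pytest.approx(
            gyration_radius_sq(r), rel=1e-9)

    def test_planar_ring_has_vanishing_smallest_eigenvalue(self):
        circ = generate_fixture("planar_circle")
        lam = gyration_tensor(circ)
        assert lam[0] == pytest.approx(0.0, abs=1e-12)
        assert lam[2] > 0

    def test_rod_has_two_vanishing_eigenvalues(self):
        rod = generate_fixture("straight_rod")
        lam = gyration_tensor(rod)
        assert lam[0] == pytest.approx(0.0, abs=1e-12)
        assert lam[1] == pytest.approx(0.0, abs=1e-12)


class TestMagneticRadius:
    def test_circle_recovers_radius_with_refinement(self):
        r64 = np.sqrt(magnetic_radius_sq(generate_fixture("planar_circle", n=64)))
        r512 = np.sqrt(magnetic_radius_sq(generate_fixture("planar_circle", n=512)))
        assert r64 == pytest.approx(3.0, rel=2e-3)
        assert abs(r512 - 3.0) < abs(r64 - 3.0)

    def test_figure_eight_cancels(self):
        assert magnetic_radius_sq(generate_fixture("figure_eight")) == \
            pytest.approx(0.0, abs=1e-9)

    def test_translation_invariance(self):
        ring = generate_fixture("planar_circle", n=32)
        shifted = ring + np.array([57.0, -31.0, 12.0])
        assert magnetic_radius_sq(shifted) == pytest.approx(
            magnetic_radius_sq(ring), rel=1e-9)
        assert np.allclose(oriented_area(shifted), oriented_area(ring))

    def test_open_chain_rejected(self):
        with pytest.raises(ValueError):
            magnetic_radius_sq(np.zeros((2, 3)))


class TestDoubleFoldReference:
    def test_printed_values(self):
        assert double_fold_reference(0.5) == pytest.approx(1.0 / 3.0)
        assert double_fold_reference(1.5) == -1.0

    def test_continuity_at_fold_scale(self):
        assert double_fold_reference(1 - 1e-9) == pytest.approx(-1.0, abs=1e-6)

    def test_domain(self):
        for z in (0.0, 2.0, -1.0, 2.5):
            with pytest.raises(ValueError):
                double_fold_reference(z)

    def test_matches_filament_fixture_correlation(self):
        # independent oracle: directly correlate the hairpin's bonds
        fil = generate_fixture("double_folded_filament", half_length=40)
        d = np.diff(fil, axis=0) / A
        half = 40.0
        for n in (10, 30, 50, 70):
            c = (d[:-n] * d[n:]).sum(axis=1).mean()
            assert c == pytest.approx(double_fold_reference(n / half), abs=1e-9)


class TestBondCorrelation:
    def test_straight_rod_fully_correlated(self):
        from ringmelt.melt_state import MeltConfiguration, Trajectory
        k = np.arange(30)
        rod = np.array(np.c_[k, k, np.zeros_like(k)], dtype=np.int64)
        cfg = MeltConfiguration(coords=np.mod(rod, 1000),
                                chains=np.arange(30)[None, :],
                                box=(1000, 1000, 1000), topology="linear")
        traj = Trajectory(times=np.array([1.0]), coords=rod[None], config=cfg)
        ell, c = bond_correlation(traj, b=1.0)
        assert np.allclose(c, 1.0)

    def test_double_folded_ring_reaches_full_anticorrelation(self):
        # exactly double-folded loop on the lattice: out along (1,1,0) and
        # straight back; the correlation minimum at the fold scale is -1
        from ringmelt.melt_state import MeltConfiguration, Trajectory
        xs = np.arange(21)
        path = np.r_[xs, xs[::-1][1:-1]]
        pos = np.array(np.c_[path, path, np.zeros_like(path)], dtype=np.int64)
        cfg = MeltConfiguration(coords=np.mod(pos, 1000),
                                chains=np.arange(len(pos))[None, :],
                                box=(1000, 1000, 1000), topology="ring")
        traj = Trajectory(times=np.array([1.0]), coords=pos[None], config=cfg)
        ell, c = bond_correlation(traj, b=1.0)
        assert c.min() == pytest.approx(-1.0)


class TestContactProbability:
    def test_adjacent_monomers_always_in_contact(self, ring_melt_trajectory):
        res = contact_probability(ring_melt_trajectory, skip=5)
        assert res["p"][0] == pytest.approx(1.0)
        assert np.all(res["p"] >= 0) and np.all(res["p"] <= 1)

    def test_zeta_symmetric_under_arc_exchange(self):
        N, N_e = 120, 10.0
        n = np.arange(1, N)
        zeta = zeta_transform(n, N, N_e)
        assert np.allclose(zeta, zeta[::-1])

    def test_contacts_decay_with_separation(self, ring_melt_trajectory):
        res = contact_probability(ring_melt_trajectory, skip=5)
        assert res["p"][-1] < res["p"][0]


class TestFitScaling:
    def test_exact_power_laws(self):
        x = np.logspace(0, 2, 12)
        for alpha in (2.0 / 3.0, 6.0 / 5.0, 1.0):
            slope, err = fit_scaling(x, x ** alpha)
            assert slope == pytest.approx(alpha, abs=1e-12)

    def test_noisy_power_law_within_interval(self, rng):
        x = np.logspace(0, 2, 20)
        y = x ** 0.7 * np.exp(rng.normal(0, 0.05, size=20))
        slope, err = fit_scaling(x, y)
        assert abs(slope - 0.7) < 3 * err + 0.02

    def test_self_consistency_of_contact_exponent(self):
        # p_c = zeta^-1 must fit gamma = 1
        zeta = np.linspace(0.5, 20, 50)
        slope, _ = fit_scaling(zeta, 1.0 / zeta)
        assert slope == pytest.approx(-1.0, abs=1e-9)

    def test_insufficient_span_rejected(self):
        x = np.array([1.0, 1.1, 1.2, 1.3])
        with pytest.raises(ValueError):
            fit_scaling(x, x ** 2)
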