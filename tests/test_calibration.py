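"""Entanglement-unit system: identities, crossover formula, estimators."""

import numpy as np
import pytest

from ringmelt.calibration import (
    REFERENCE_CALIBRATION,
    EntanglementUnits,
    entanglement_length,
    entanglement_time,
    estimate_kuhn_length,
    mean_bond_length,
    tube_diameter,
    validate_crossover_formula,
)
from ringmelt.fcc_lattice import A, neighbor_vectors
from ringmelt.melt_state import MeltConfiguration, Trajectory


def _trajectory_from_chain(pos, topology="linear", n_snapshots=1):
    pos = np.asarray(pos, dtype=np.int64)
    cfg = MeltConfiguration(coords=np.mod(pos, 10 ** 6),
                            chains=np.arange(len(pos))[None, :],
                            box=(10 ** 6, 10 ** 6, 10 ** 6),
                            topology=topology)
    coords = np.repeat(pos[None, :, :], n_snapshots, axis=0)
    return Trajectory(times=np.arange(n_snapshots, dtype=float) + 1.0,
                      coords=coords, config=cfg)


class TestMeanBondLength:
    def test_all_effective_bonds_give_a(self):
        v = neighbor_vectors()
        pos = np.cumsum(np.vstack([[0, 0, 0], v[[0, 1, 4, 8, 5]]]), axis=0)
        traj = _trajectory_from_chain(pos)
        assert mean_bond_length(traj) == pytest.approx(1.0)

    def test_half_stored_gives_half_a(self):
        v = neighbor_vectors()
        steps = np.zeros((8, 3), dtype=np.int64)
        steps[::2] = v[[0, 1, 4, 8]]        # alternate bond / stored unit
        pos = np.cumsum(np.vstack([[0, 0, 0], steps]), axis=0)
        traj = _trajectory_from_chain(pos)
        assert mean_bond_length(traj) == pytest.approx(0.5)

    def test_empty_trajectory_rejected(self):
        pos = np.zeros((4, 3), dtype=np.int64)
        traj = _trajectory_from_chain(pos)
        with pytest.raises(ValueError):
            mean_bond_length(traj, skip=5)


class TestCrossoverFormula:
    def test_reproduces_reference_entanglement_lengths(self):
        assert validate_crossover_formula(rtol=0.005)

    def test_ratio_decreasing_in_overlap_number(self):
        n = np.linspace(0.5, 50, 200)
        ratio = [entanglement_length(1.0, x) for x in n]
        assert np.all(np.diff(ratio) < 0)

    def test_limiting_exponents(self):
        # loose: L_e/l_K ~ n_K^-2 at small n_K; tight: ~ n_K^-2/5 at large
        lo = np.log(entanglement_length(1, 1e-4) / entanglement_length(1, 2e-4)) / np.log(2)
        hi = np.log(entanglement_length(1, 1e4) / entanglement_length(1, 2e4)) / np.log(2)
        assert lo == pytest.approx(2.0, abs=0.01)
        assert hi == pytest.approx(0.4, abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            entanglement_length(-1.0, 2.0)
        with pytest.raises(ValueError):
            tube_diameter(0.0, 1.0)


class TestEntanglementUnits:
    @pytest.mark.parametrize("kappa", [0.0, 1.0, 2.0])
    def test_internal_identities(self, kappa):
        u = EntanglementUnits.from_reference(kappa)
        assert u.N_e * u.b == pytest.approx(u.L_e)
        assert u.d_T ** 2 == pytest.approx(u.l_K * u.L_e / 6.0)
        assert u.n_K == pytest.approx(u.rho * u.b * u.l_K ** 2)

    def test_tube_diameter_special_point(self):
        # L_e = 6 l_K makes d_T = l_K exactly
        assert tube_diameter(6.0 * 2.5, 2.5) == pytest.approx(2.5)

    def test_unit_conversions(self):
        u = EntanglementUnits.from_reference(0.0)
        assert u.z(u.L_e) == pytest.approx(1.0)
        assert u.Z(640) == pytest.approx(640 / u.N_e)
        assert u.in_tube_units(u.d_T) == pytest.approx(1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            EntanglementUnits(kappa_bend=0.0, b=-1.0, l_K=1.0)


class TestKuhnLengthEstimator:
    def test_freely_jointed_chain_recovers_bond_length(self, rng):
        # ideal FJC on the fcc lattice: <R^2(n)> = n a^2, so the plateau of
        # <R^2>/l with l = n a is exactly a
        v = neighbor_vectors()
        chains = []
        n_chains, n_steps = 64, 500
        for _ in range(n_chains):
            steps = v[rng.integers(0, 12, size=n_steps)]
            chains.append(np.cumsum(np.vstack([[0, 0, 0], steps]), axis=0))
        pos = np.vstack(chains)
        cfg = MeltConfiguration(
            coords=np.mod(pos, 10 ** 6),
            chains=np.arange(len(pos)).reshape(n_chains, n_steps + 1),
            box=(10 ** 6, 10 ** 6, 10 ** 6), topology="linear")
        traj = Trajectory(times=np.array([1.0]), coords=pos[None], config=cfg)
        l_K, diag = estimate_kuhn_length(traj, fit_window=(150, 200))
        assert l_K == pytest.approx(1.0, rel=0.1)
        assert diag["reliable"]

    def test_rod_flagged_unreliable(self):
        v = neighbor_vectors()
        pos = np.cumsum(np.vstack([np.zeros((1, 3), int)] + [v[:1]] * 300), axis=0)
        traj = _trajectory_from_chain(pos)
        l_K, diag = estimate_kuhn_length(traj, fit_window=(150, 200))
        assert not diag["reliable"]

    def test_short_chains_rejected(self):
        v = neighbor_vectors()
        pos = np.cumsum(np.vstack([np.zeros((1, 3), int)] + [v[:1]] * 30), axis=0)
        traj = _trajectory_from_chain(pos)
        with pytest.raises(ValueError):
            estimate_kuhn_length(traj, fit_window=(150, 200))


class TestEntanglementTime:
    def test_closed_form_inversion(self):
        # g1 = c tau^1/2 with c chosen so g1(100) = d_T^2
        d_T = 3.0
        tau = np.logspace(0, 4, 60)
        g1 = (d_T ** 2 / 10.0) * tau ** 0.5
        assert entanglement_time(tau, g1, d_T) == pytest.approx(100.0, rel=1e-6)

    def test_monotone_in_tube_diameter(self):
        tau = np.logspace(0, 4, 60)
        g1 = 0.5 * tau ** 0.5
        t1 = entanglement_time(tau, g1, 2.0)
        t2 = entanglement_time(tau, g1, 3.0)
        assert t2 > t1

    def test_no_bracketing_rejected(self):
        tau = np.logspace(0, 2, 10)
        g1 = 1e-6 * tau ** 0.5
        with pytest.raises(ValueError):
            entanglement_time(tau, g1, 100.0)


class TestReferenceTable:
    def test_reference_rows_are_self_consistent(self):
        for kappa, row in REFERENCE_CALIBRATION.items():
            u = EntanglementUnits.from_reference(kappa)
            assert u.n_K == pytest.approx(row["n_K"], rel=0.005)
            assert u.L_e == pytest.approx(row["L_e"], rel=0.005)
            assert u.N_e == pytest.approx(row["N_e"], rel=0.005)
            assert u.d_T == pytest.approx(row["d_T"], rel=0.005)
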