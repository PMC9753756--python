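"""Kinetic Monte Carlo dynamics: moves, constraints, reproducibility."""

import warnings

import numpy as np
import pytest

from ringmelt.fcc_lattice import neighbor_vectors
from ringmelt.kmc_engine import (
    MoveOutcome,
    SimulationParams,
    attempt_move,
    pin_rings,
    run,
)
from ringmelt.melt_state import (
    MeltConfiguration,
    build_linear_melt,
    build_ring_melt,
    linking_matrix,
    validate,
)


class TestSimulationParams:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            SimulationParams(sweeps=-1)
        with pytest.raises(ValueError):
            SimulationParams(pin_fraction=1.5)

    def test_linear_schedule(self):
        p = SimulationParams(sweeps=100, snapshot_every=25)
        assert list(p.schedule()) == [25, 50, 75, 100]

    def test_log_schedule_spans_run(self):
        p = SimulationParams(sweeps=1000, log_snapshots=True)
        s = p.schedule()
        assert s[0] == 1 and s[-1] == 1000
        assert np.all(np.diff(s) > 0)


class TestRun:
    def test_zero_sweeps_yields_initial_snapshot_only(self, small_ring_melt):
        traj = run(small_ring_melt, SimulationParams(sweeps=0, seed=1))
        assert traj.n_snapshots == 1
        assert np.array_equal(
            np.mod(traj.coords[0], np.array(small_ring_melt.box)),
            small_ring_melt.coords)

    def test_same_seed_identical_trajectories(self, small_ring_melt):
        p = SimulationParams(sweeps=200, snapshot_every=50, seed=42)
        t1 = run(small_ring_melt, p)
        t2 = run(small_ring_melt, p)
        assert np.array_equal(t1.coords, t2.coords)

    def test_different_seed_differs(self, small_ring_melt):
        t1 = run(small_ring_melt, SimulationParams(sweeps=200, seed=1))
        t2 = run(small_ring_melt, SimulationParams(sweeps=200, seed=2))
        assert not np.array_equal(t1.coords[-1], t2.coords[-1])

    def test_conservation_laws(self, small_ring_melt):
        traj = run(small_ring_melt,
                   SimulationParams(sweeps=500, snapshot_every=100, seed=3))
        final = traj.info["final_config"]
        assert final.n_monomers == small_ring_melt.n_monomers
        assert final.n_chains == small_ring_melt.n_chains
        assert final.box == small_ring_melt.box
        assert validate(final).ok

    def test_fully_pinned_melt_is_frozen(self, small_ring_melt):
        cfg = pin_rings(small_ring_melt, 1.0, 0)
        traj = run(cfg, SimulationParams(sweeps=100, snapshot_every=50, seed=5))
        assert np.array_equal(traj.coords[0], traj.coords[-1])

    def test_occupancy_histogram_stays_legal(self, small_ring_melt):
        traj = run(small_ring_melt,
                   SimulationParams(sweeps=300, snapshot_every=300, seed=6))
        snap = traj.snapshot(-1)
        occ = snap.site_occupants()
        assert max(len(v) for v in occ.values()) <= 2

    def test_flexible_moves_never_metropolis_rejected(self, small_ring_melt):
        # at kappa = 0 with uniform stored-length weight the Metropolis
        # factor is always 1: every constraint-satisfying move is accepted
        traj = run(small_ring_melt,
                   SimulationParams(sweeps=200, snapshot_every=200, seed=7))
        assert traj.info["rejections"]["metropolis"] == 0

    def test_stiff_moves_are_metropolis_filtered(self):
        cfg = build_ring_melt(M=4, N=40, occupancy=1.25, kappa_bend=2.0, seed=1)
        traj = run(cfg, SimulationParams(sweeps=500, snapshot_every=500, seed=8))
        assert traj.info["rejections"]["metropolis"] > 0


class TestPinning:
    def test_zero_fraction_empty_set(self, small_ring_melt):
        assert pin_rings(small_ring_melt, 0.0, 0).pinned == set()

    def test_half_fraction_pins_half(self, small_ring_melt):
        pinned = pin_rings(small_ring_melt, 0.5, 0).pinned
        assert len(pinned) == small_ring_melt.n_chains // 2

    def test_same_seed_same_set(self, small_ring_melt):
        a = pin_rings(small_ring_melt, 0.4, 9).pinned
        b = pin_rings(small_ring_melt, 0.4, 9).pinned
        assert a == b

    def test_linear_topology_unsupported(self):
        cfg = build_linear_melt(M=2, N=30, occupancy=1.0, seed=1)
        with pytest.raises(ValueError):
            pin_rings(cfg, 0.5, 0)


class TestAttemptMove:
    def test_outcome_reports_single_reason(self, small_ring_melt):
        seen = set()
        for s in range(60):
            outcome, _ = attempt_move(small_ring_melt, s)
            assert isinstance(outcome, MoveOutcome)
            if outcome.accepted:
                assert outcome.reason == "accepted"
            else:
                assert outcome.reason in {"connectivity", "excluded volume",
                                          "metropolis", "pinned"}
            seen.add(outcome.reason)
        assert "accepted" in seen        # some moves must go through

    def test_accepted_move_changes_exactly_one_monomer(self, small_ring_melt):
        for s in range(80):
            outcome, cfg = attempt_move(small_ring_melt, s)
            if outcome.accepted:
                moved = np.any(cfg.coords != small_ring_melt.coords, axis=1)
                assert moved.sum() == 1
                assert moved[outcome.monomer]
                assert validate(cfg).ok
                break
        else:  # pragma: no cover
            pytest.fail("no accepted move in 80 attempts")


class TestTopologyConservation:
    def test_linking_matrix_zero_along_run(self, small_ring_melt):
        traj = run(small_ring_melt,
                   SimulationParams(sweeps=600, snapshot_every=200, seed=12))
        for s in range(traj.n_snapshots):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lk = linking_matrix(traj.snapshot(s))
            assert np.all(lk == 0)


class TestMeltAngleStatistics:
    def test_flexible_melt_is_stiffer_than_ideal(self, ring_melt_trajectory):
        # excluded volume induces bond alignment: <cos> > 0 at kappa = 0,
        # where the ideal chain has <cos> = 0 exactly
        from ringmelt.calibration import mean_bond_cosine
        assert mean_bond_cosine(ring_melt_trajectory, skip=5) > 0.02
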