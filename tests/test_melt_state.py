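"""Melt construction, validation, topology and I/O."""

import io
import warnings

import numpy as np
import pytest

from ringmelt.fcc_lattice import A
from ringmelt.fixtures import generate_fixture
from ringmelt.melt_state import (
    MeltConfiguration,
    MeltConstructionError,
    build_linear_melt,
    build_ring_melt,
    linking_matrix,
    linking_number,
    read_snapshot,
    read_trajectory,
    unwrap,
    validate,
    wrap,
    write_snapshot,
    write_trajectory,
)
from ringmelt.kmc_engine import SimulationParams, run


class TestBuilders:
    def test_small_ring_melt_is_valid_and_unlinked(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = build_ring_melt(M=2, N=24, occupancy=1.25, seed=7)
        assert validate(cfg).ok
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert np.all(linking_matrix(cfg) == 0)

    def test_melt_density_matches_request(self):
        cfg = build_ring_melt(M=8, N=100, occupancy=1.25, seed=1)
        assert cfg.occupancy == pytest.approx(1.25, rel=0.02)
        # rho a^3 = occupancy * sqrt(2): the fcc site volume is a^3/sqrt(2)
        assert cfg.monomer_density == pytest.approx(1.77, rel=0.02)

    def test_same_seed_reproduces_configuration(self):
        a = build_ring_melt(M=4, N=40, occupancy=1.25, seed=3)
        b = build_ring_melt(M=4, N=40, occupancy=1.25, seed=3)
        assert np.array_equal(a.coords, b.coords)
        assert a.box == b.box

    def test_linear_melt_single_dilute_chain(self):
        cfg = build_linear_melt(M=1, N=30, occupancy=0.5, seed=2)
        assert validate(cfg).ok
        assert cfg.topology == "linear"

    def test_linear_chain_ends_are_free(self):
        cfg = build_linear_melt(M=2, N=30, occupancy=1.0, seed=2)
        # the end-to-end site displacement need not be a bond: only N-1
        # bonds are validated; breaking the would-be closure must not
        # invalidate the config
        assert validate(cfg).ok

    def test_infeasible_occupancy_rejected(self):
        with pytest.raises(MeltConstructionError):
            build_ring_melt(M=2, N=24, occupancy=3.0, seed=0)
        with pytest.raises(MeltConstructionError):
            build_ring_melt(M=2, N=2, occupancy=1.0, seed=0)


class TestValidation:
    def _tiny_ring(self):
        # valid 6-monomer ring on a triangle with three stored units
        tri = np.array([(0, 0, 0), (1, 1, 0), (1, 0, 1)], dtype=np.int64)
        coords = np.repeat(tri, 2, axis=0)
        return MeltConfiguration(coords=coords,
                                 chains=np.arange(6)[None, :],
                                 box=(6, 6, 6), topology="ring")

    def test_fresh_build_has_empty_report(self):
        assert validate(self._tiny_ring()).ok

    def test_nonconsecutive_site_sharing_reported(self):
        cfg = self._tiny_ring()
        cfg.coords[4] = cfg.coords[0]     # monomer 4 joins site of 0/1
        rep = validate(cfg)
        assert not rep.ok
        assert any("share" in e or "holds" in e for e in rep.errors)

    def test_three_consecutive_on_one_site_reported(self):
        cfg = self._tiny_ring()
        cfg.coords[2] = cfg.coords[0]     # monomers 0,1,2 on one site
        rep = validate(cfg)
        assert not rep.ok
        assert any("consecutive" in e or "holds" in e for e in rep.errors)

    def test_odd_box_reported(self):
        cfg = self._tiny_ring()
        cfg.box = (5, 6, 6)
        assert not validate(cfg).ok


class TestLinkingNumber:
    def test_distant_coplanar_squares_unlinked(self):
        sq = np.array([[0, 0, 0], [3, 0, 0], [3, 3, 0], [0, 3, 0]], float)
        assert linking_number(sq, sq + np.array([10.0, 0, 0])) == 0

    def test_hopf_link_is_unit(self):
        a, b = generate_fixture("hopf_link")
        assert abs(linking_number(a, b)) == 1

    def test_threaded_but_unlinked_pair(self):
        a, b = generate_fixture("threaded_pair")
        assert linking_number(a, b) == 0

    def test_open_curve_rejected(self):
        rod = generate_fixture("straight_rod")
        sq = np.array([[0, 0, 5], [3, 0, 5], [3, 3, 5], [0, 3, 5]], float)
        with pytest.raises(ValueError):
            linking_number(rod[:2], sq)

    def test_melt_linking_matrix_symmetric_zero(self, small_ring_melt):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lk = linking_matrix(small_ring_melt)
        assert np.array_equal(lk, lk.T)
        assert np.all(lk == 0)


class TestUnwrap:
    def test_round_trip_rewrap(self, small_ring_melt):
        up = unwrap(small_ring_melt)
        assert np.array_equal(wrap(up, small_ring_melt.box),
                              small_ring_melt.coords)

    def test_ring_closure_in_unwrapped_space(self, small_ring_melt):
        up = unwrap(small_ring_melt)
        for c in range(small_ring_melt.n_chains):
            p = up[small_ring_melt.chains[c]]
            closure = p[0] - p[-1]
            assert (closure ** 2).sum() in (0, 2)

    def test_bonds_have_length_zero_or_a(self, small_ring_melt):
        up = unwrap(small_ring_melt)
        for c in range(small_ring_melt.n_chains):
            p = up[small_ring_melt.chains[c]]
            d2 = (np.diff(p, axis=0) ** 2).sum(axis=1)
            assert set(np.unique(d2)) <= {0, 2}


class TestSnapshotIO:
    def test_snapshot_round_trip_bit_exact(self, small_ring_melt):
        buf = io.StringIO()
        write_snapshot(small_ring_melt, buf)
        text1 = buf.getvalue()
        back = read_snapshot(io.StringIO(text1))
        assert np.array_equal(back.coords, small_ring_melt.coords)
        assert back.box == small_ring_melt.box
        assert back.kappa_bend == small_ring_melt.kappa_bend
        buf2 = io.StringIO()
        write_snapshot(back, buf2)
        assert buf2.getvalue() == text1

    def test_trajectory_round_trip(self, small_ring_melt):
        traj = run(small_ring_melt,
                   SimulationParams(sweeps=50, snapshot_every=25, seed=4))
        buf = io.StringIO()
        write_trajectory(traj, buf)
        back = read_trajectory(io.StringIO(buf.getvalue()))
        assert np.array_equal(back.times, traj.times)
        assert np.array_equal(back.coords, traj.coords)
        buf2 = io.StringIO()
        write_trajectory(back, buf2)
        assert buf2.getvalue() == buf.getvalue()

    def test_bad_header_rejected(self):
        with pytest.raises(ValueError):
            read_snapshot(io.StringIO("#NOTAMELT 1\n"))
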