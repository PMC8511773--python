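"""Allee thresholds, basin membership and basin-instability classes."""

import numpy as np
import pytest

from phasetip import cycles, models
from phasetip.basins import (allee_threshold, basin_unstable_phases,
                             bi_region, classify_basin_instability,
                             in_basin, union_of_cycles)


@pytest.fixture(scope="module")
def rma_theta(rma):
    """theta(2.47) for the RMA model."""
    return allee_threshold(rma.with_r(2.47))


class TestAlleeThreshold:
    def test_anchored_at_allee_saddle(self, rma_theta):
        assert rma_theta.saddle.label == "e2"
        d = np.hypot(rma_theta.polyline[:, 0] - 0.03,
                     1e3 * rma_theta.polyline[:, 1])
        assert d.min() < 1e-5  # polyline passes through e2 = (mu, 0)

    def test_may_anchored_at_coexistence_saddle(self, may):
        th = allee_threshold(may.with_r(2.0))
        assert th.saddle.label == "e4"

    def test_polyline_points_flow_to_saddle(self, rma, rma_theta):
        # defining property of the stable manifold: forward orbits from
        # the polyline pass arbitrarily close to the saddle
        from phasetip import _core
        sad = rma_theta.saddle.location
        idx = np.linspace(0, len(rma_theta.polyline) - 1, 12).astype(int)
        for i in idx:
            x0 = rma_theta.polyline[i]
            ts = np.linspace(0.0, 40.0, 2001)
            tr = _core.integrate_dense(rma.model_id, rma.to_array(), 2.47,
                                       x0[0], x0[1], ts, 1e-10, 1e-13)
            d = np.hypot(tr[:, 0] - sad[0], 1e3 * (tr[:, 1] - sad[1]))
            assert d.min() < 0.05

    def test_saddle_required(self, rma):
        # below the oscillatory-coexistence region there is no cycle to
        # bound, and the constructor refuses to guess a truncation box
        with pytest.raises(ValueError):
            allee_threshold(rma.with_r(1.2))

    def test_extinction_side_orientation(self, rma, rma_theta):
        # high-predator states above the threshold are extinction-bound
        assert rma_theta.is_extinction_side([[1.0, 0.03]])[0]
        e3 = models.coexistence_equilibrium(rma)
        assert not rma_theta.is_extinction_side([e3])[0]


class TestInBasin:
    def test_point_on_cycle(self, rma, rma_cycle):
        verdict = in_basin(rma_cycle.samples[100], rma, cycle=rma_cycle)
        assert verdict == "cycle"

    def test_below_allee_density(self, rma, rma_cycle):
        # N < mu with no predator: the strong Allee effect kills the prey
        assert in_basin([0.01, 0.0], rma, cycle=rma_cycle) == "extinction"

    def test_reference_initial_condition(self, rma, rma_cycle):
        # the Monte-Carlo starting point lies in the cycle's basin
        assert in_basin([3.0, 0.002], rma, cycle=rma_cycle) == "cycle"

    def test_high_predator_extinction(self, may):
        cyc = cycles.find_limit_cycle(may.with_r(2.0), n_samples=800)
        assert in_basin([1.0, 0.04], may.with_r(2.0), cycle=cyc) \
            == "extinction"


class TestClassification:
    def test_rma_fixtures(self, rma):
        p1 = rma.with_r(2.47)
        assert classify_basin_instability(p1, rma.with_r(2.05)).klass \
            == "none"
        res = classify_basin_instability(p1, rma.with_r(1.8))
        assert res.klass == "partial"
        assert 0.0 < res.out_fraction < 1.0

    def test_may_fixtures(self, may):
        p1 = may.with_r(3.3)
        assert classify_basin_instability(p1, may.with_r(2.82)).klass \
            == "none"
        res = classify_basin_instability(p1, may.with_r(2.0))
        assert res.klass == "partial"
        # the May cycle has a noticeably wider basin-unstable portion
        assert res.out_fraction > 0.3

    def test_self_classification_none(self, rma, may):
        for p in (rma.with_r(2.47), may.with_r(3.3)):
            assert classify_basin_instability(p, p).klass == "none"

    def test_partial_persists_deeper_in_bracket(self, rma):
        # once partial at some r2, still partial at smaller r2
        p1 = rma.with_r(2.47)
        outs = [classify_basin_instability(p1, rma.with_r(r2)).out_fraction
                for r2 in (1.9, 1.85, 1.8)]
        assert all(o > 0 for o in outs)
        assert outs[-1] > outs[0]


class TestUnstablePhases:
    def test_empty_when_none(self, rma):
        arcs = basin_unstable_phases(rma.with_r(2.47), rma.with_r(2.05))
        assert arcs == []

    def test_arcs_cover_quarter_phase(self, rma, may):
        # tipping-prone phases surround phi = pi/2 in both models
        for p, r1, r2 in ((rma, 2.47, 1.8), (may, 3.3, 2.0)):
            arcs = basin_unstable_phases(p.with_r(r1), p.with_r(r2))
            assert arcs, (p.model_name, r2)

            def contains(phi):
                return any((lo <= phi <= hi) if lo <= hi
                           else (phi >= lo or phi <= hi)
                           for lo, hi in arcs)

            assert contains(np.pi / 2 + 0.2)
            assert not contains(3 * np.pi / 2)

    def test_arcs_appear_below_marginal_value(self, rma):
        p1 = rma.with_r(2.47)
        assert basin_unstable_phases(p1, rma.with_r(1.94)) == []
        assert basin_unstable_phases(p1, rma.with_r(1.90)) != []


class TestMembershipOraclesAgree:
    def test_geometry_vs_integration(self, rma, rma_cycle):
        # side-of-threshold and forward integration agree for >= 99% of
        # cycle samples away from the boundary band
        from phasetip.basins import _arc_resample, _memberships
        p2 = rma.with_r(1.8)
        c2 = cycles.find_limit_cycle(p2, n_samples=800)
        nhi = 1.5 * max(rma_cycle.bounding_box()[1], c2.bounding_box()[1])
        phi = 1.5 * max(rma_cycle.bounding_box()[3], c2.bounding_box()[3])
        theta = allee_threshold(p2, box=(0.0, nhi, 0.0, phi))
        pts = _arc_resample(rma_cycle.samples, 600)
        codes = np.asarray(_memberships(p2, pts, c2, t_max=1000.0))
        geo = theta.is_extinction_side(pts)
        away = theta.distance(pts) > 0.02
        agree = (codes == 1) == geo
        assert np.mean(agree[away]) >= 0.99


class TestBiRegion:
    def test_tiny_grid(self, rma):
        p1 = rma.with_r(2.47)
        grid = bi_region(p1, r_values=[1.8, 2.47, 2.9],
                         second_values=[2.2], second_param="delta",
                         n_samples=400)
        assert grid.shape == (1, 3)
        assert grid[0, 0] == 1    # basin unstable at lower r
        assert grid[0, 1] == 0    # p2 = p1 is never basin unstable
        assert grid[0, 2] == -1   # past r_h: no cycle, not applicable


class TestUnionOfCycles:
    def test_partition(self, rma):
        G = union_of_cycles(rma, 1.6, 2.5, n=8, n_samples=300)
        # the cycle at the lower path end is inside its own basin
        assert G.unstable_masks[0].sum() == 0
        # the family has a nonempty basin-unstable (pink) part
        assert sum(m.sum() for m in G.unstable_masks) > 0

    def test_may_nonempty_unstable_part(self, may):
        G = union_of_cycles(may, 2.0, 3.3, n=6, n_samples=300)
        assert sum(m.sum() for m in G.unstable_masks) > 0

    def test_path_leaving_interval_raises(self, rma):
        with pytest.raises(ValueError):
            union_of_cycles(rma, 1.2, 2.5, n=4, n_samples=200)
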