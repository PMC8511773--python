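"""Switching simulations, tipping detection, rescue events, ensembles."""

import numpy as np

from phasetip import cycles
from phasetip.climate import ClimatePath, ClimateSpec
from phasetip.tipping import (classify_event_amplitudes, detect_rescue,
                              detect_tipping, monte_carlo,
                              simulate_nonautonomous, single_switch_tips)


def _const_path(r, years):
    return ClimatePath(dwells=np.array([years], dtype=np.int64),
                       amplitudes=np.array([float(r)]))


class TestSimulate:
    def test_cycle_invariance_under_constant_input(self, rma, rma_cycle):
        from phasetip.basins import _arc_resample
        path = _const_path(2.47, 100)
        traj = simulate_nonautonomous(rma, path, rma_cycle.samples[0])
        ref = _arc_resample(rma_cycle.samples, 8000)  # dense in fast arcs
        d = np.hypot(
            traj.states[:, 0][:, None] - ref[None, :, 0],
            1e3 * (traj.states[:, 1][:, None] - ref[None, :, 1]))
        assert d.min(axis=1).max() < 0.05

    def test_prey_only_subspace(self, rma):
        # P(0) = 0 stays exactly zero under any forcing (RMA)
        path = ClimatePath(dwells=np.array([3, 4, 5]),
                           amplitudes=np.array([1.7, 2.4, 2.0]))
        traj = simulate_nonautonomous(rma, path, np.array([3.0, 0.0]))
        assert np.all(traj.states[:, 1] == 0.0)

    def test_state_continuous_across_switches(self, rma):
        path = ClimatePath(dwells=np.array([5, 5]),
                           amplitudes=np.array([2.47, 1.9]))
        traj = simulate_nonautonomous(rma, path, np.array([3.0, 0.002]),
                                      dt=0.05)
        k = np.searchsorted(traj.times, 5.0)
        assert np.allclose(traj.states[k], traj.switch_states[1],
                           atol=1e-6)


class TestDetectTipping:
    def test_none_when_tracking(self, rma, rma_rh):
        path = _const_path(2.47, 200)
        ev = detect_tipping(rma, path, np.array([3.0, 0.002]), rh=rma_rh)
        assert ev is None

    def test_single_switch_from_unstable_phase(self, rma, rma_cycle,
                                               rma_rh):
        x0 = rma_cycle.state_at_phase(np.pi / 2)
        path = ClimatePath(dwells=np.array([200]),
                           amplitudes=np.array([1.8]))
        ev = detect_tipping(rma, path, x0, rh=rma_rh)
        assert ev is not None
        assert ev.klass == "P"
        assert ev.t1 == 0.0

    def test_single_switch_from_stable_phase(self, rma, rma_cycle,
                                             rma_rh):
        x0 = rma_cycle.state_at_phase(3 * np.pi / 2)
        path = ClimatePath(dwells=np.array([200]),
                           amplitudes=np.array([1.8]))
        assert detect_tipping(rma, path, x0, rh=rma_rh) is None

    def test_attribution_to_causal_switch(self, rma, rma_cycle, rma_rh):
        # settle on the cycle for 40 years, then drop into the
        # basin-unstable configuration: the second switch is causal
        x0 = rma_cycle.state_at_phase(0.0)
        dwell1 = 41  # whole years on Gamma(2.47)
        path = ClimatePath(dwells=np.array([dwell1, 300]),
                           amplitudes=np.array([2.47, 1.6]))
        ev = detect_tipping(rma, path, x0, rh=rma_rh)
        if ev is not None:  # tips only if the switch lands in the arc
            assert ev.t1 in (0.0, float(dwell1))
            assert ev.r_post in (2.47, 1.6)


class TestClassify:
    def test_amplitude_rule(self, rma_rh):
        assert classify_event_amplitudes(2.65, rma_rh) == "B"
        assert classify_event_amplitudes(1.7, rma_rh) == "P"
        assert classify_event_amplitudes(2.65, None) == "P"  # May rule


class TestRescue:
    def test_single_switch_has_no_rescue(self, rma, rma_cycle):
        x0 = rma_cycle.state_at_phase(np.pi / 2)
        path = _const_path(1.8, 100)
        assert detect_rescue(rma, path, x0) == []

    def test_constructed_rescue(self, rma, rma_cycle):
        # drop into the basin-unstable configuration for one year, then
        # restore: the state exits B(Gamma, 1.8) but re-enters
        # B(Gamma, 2.47) before extinction
        from phasetip.basins import in_basin
        x0 = rma_cycle.state_at_phase(np.pi / 2)
        path = ClimatePath(dwells=np.array([1, 80]),
                           amplitudes=np.array([1.8, 2.47]))
        rescues = detect_rescue(rma, path, x0)
        assert len(rescues) == 1
        assert rescues[0].start_segment == 0
        # oracle: the state one year in really is outside B(Gamma(1.8))
        traj = simulate_nonautonomous(rma, path, x0)
        x1 = traj.switch_states[1]
        assert in_basin(x1, rma.with_r(1.8)) == "extinction"
        assert in_basin(x1, rma.with_r(2.47)) == "cycle"

    def test_rescues_occur_in_random_forcing(self, rma):
        # multi-switch paths on [1.6, 2.5] produce rescue events; they
        # are rare (roughly one per 30 x 2000 yr of forcing), so scan a
        # fixed window of realizations that contains one
        from phasetip.climate import generate_path
        found = 0
        for seed in range(8, 13):
            path = generate_path(ClimateSpec(r_low=1.6, r_high=2.5,
                                             rho=0.2, horizon=2000.0,
                                             seed=seed))
            found += len(detect_rescue(rma, path, np.array([3.0, 0.002])))
        assert found > 0


class TestSingleSwitch:
    def test_no_switch_no_tip(self, rma, rma_cycle):
        for phi in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            assert single_switch_tips(rma, 2.47, 2.47, phi,
                                      cycle1=rma_cycle,
                                      cycle2=rma_cycle) is False

    def test_fixture_phases(self, rma, rma_cycle):
        c2 = cycles.find_limit_cycle(rma.with_r(1.8), n_samples=800)
        assert single_switch_tips(rma, 2.47, 1.8, np.pi / 2,
                                  cycle1=rma_cycle, cycle2=c2) is True
        assert single_switch_tips(rma, 2.47, 1.8, 3 * np.pi / 2,
                                  cycle1=rma_cycle, cycle2=c2) is False

    def test_no_instability_no_tip_any_phase(self, rma, rma_cycle):
        c2 = cycles.find_limit_cycle(rma.with_r(2.05), n_samples=800)
        for phi in np.linspace(0, 2 * np.pi, 24, endpoint=False):
            assert single_switch_tips(rma, 2.47, 2.05, phi,
                                      cycle1=rma_cycle, cycle2=c2) is False


class TestMonteCarlo:
    def test_counts_reconcile(self, rma_ensemble):
        # every run ends in exactly one of {event, horizon reached}
        assert rma_ensemble.n_runs == (rma_ensemble.n_events
                                       + rma_ensemble.n_no_tip)

    def test_reproducible(self, rma, rma_rh):
        spec = ClimateSpec(r_low=1.6, r_high=2.5, rho=0.2, horizon=5000.0)
        a = monte_carlo(rma, spec, (3.0, 0.002), 10, seed=99, rh=rma_rh)
        b = monte_carlo(rma, spec, (3.0, 0.002), 10, seed=99, rh=rma_rh)
        assert a.to_frame().equals(b.to_frame())

    def test_mixed_classes_when_interval_contains_rh(self, rma, rma_rh):
        # forcing through the dangerous bifurcation yields both classes
        spec = ClimateSpec(r_low=1.6, r_high=2.7, rho=0.2, horizon=5000.0)
        res = monte_carlo(rma, spec, (3.0, 0.002), 60, seed=17, rh=rma_rh)
        counts = res.counts()
        assert counts["B"] > 0 and counts["P"] > 0
        df = res.to_frame()
        b = df[df["class"] == "B"]
        assert (b.r_post > rma_rh).all()
        assert (df[df["class"] == "P"].r_post <= rma_rh).all()

    def test_b_phases_track_measure_p_phases_do_not(self, rma, rma_rh):
        # B-tipping phases follow the invariant measure; P-tipping
        # phases concentrate near pi/2 regardless of it
        from phasetip.cycles import invariant_measure
        from phasetip.report import report_ensemble
        spec = ClimateSpec(r_low=1.6, r_high=2.7, rho=0.2, horizon=5000.0)
        res = monte_carlo(rma, spec, (3.0, 0.002), 150, seed=23,
                          rh=rma_rh)
        cyc = cycles.find_limit_cycle(rma.with_r(0.5 * (1.6 + 2.7)))
        bundle = report_ensemble(res, invariant_measure(cyc, 16),
                                 n_bins=16)
        corr = bundle["correlation"]
        assert corr["B"] > corr["P"]
        df = res.to_frame()
        p_ph = df.loc[df["class"] == "P", "phase"]
        assert np.abs(p_ph - np.pi / 2).median() < 0.8
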