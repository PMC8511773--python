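"""Non-autonomous switching simulations and tipping detection.

The non-autonomous predator-prey system follows the frozen vector field
with r fixed within each climate segment and switches r instantaneously
at whole-year boundaries; the state is continuous across switches.  A
collapse is attributed to the last switch before irreversible entry
into the extinction basin: the tipping time t1 is the smallest switch
time after which the state never re-enters the basin of the cycle of
the currently frozen system.

Events are classified by comparing the post-switch amplitude with the
dangerous heteroclinic level r_h of the cycle: bifurcation-driven
(B) tipping requires r_post > r_h; everything else -- in particular
every collapse under decreasing r, and every collapse in the May model,
which has no dangerous cycle bifurcation -- is phase (P) tipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core
from .climate import ClimatePath, ClimateSpec, generate_path
from .cycles import LimitCycle, find_limit_cycle, phase_of
from .models import ModelParams, coexistence_equilibrium, extinction_state

__all__ = [
    "Trajectory",
    "TippingEvent",
    "RescueEvent",
    "simulate_nonautonomous",
    "detect_tipping",
    "classify_event",
    "detect_rescue",
    "single_switch_tips",
    "monte_carlo",
    "MonteCarloResult",
]

#: frozen-system integration horizon used for membership verdicts (yr);
#: a state that has not reached the extinction ball by then is treated
#: as inside the cycle's basin
T_SETTLE = 400.0

_RTOL, _ATOL = 1e-8, 1e-10


@dataclass(frozen=True)
class Trajectory:
    """A switching run: dense output plus the exact states at switches."""

    times: np.ndarray
    states: np.ndarray
    path: ClimatePath
    switch_states: np.ndarray
    params: ModelParams
    extinct_segment: int = -1
    t_extinct: float = -1.0


def _run_switching(p: ModelParams, path: ClimatePath, x0):
    e0 = extinction_state(p)
    x0 = np.asarray(x0, dtype=float)
    return _core.simulate_switching(
        p.model_id, p.to_array(), path.dwells.astype(np.float64),
        path.amplitudes, float(x0[0]), float(x0[1]), e0[0], e0[1],
        _RTOL, _ATOL)


def simulate_nonautonomous(p: ModelParams, path: ClimatePath, x0,
                           t0: float = 0.0, dt: float = 0.1) -> Trajectory:
    """Integrate the switching system over the whole path.

    Dense output every dt years; r is frozen per segment and the state
    is passed continuously across switches.  t0 shifts the reported
    time axis only.
    """
    sw, ext_seg, t_ext, *_ = _run_switching(p, path, x0)
    q = p.to_array()
    times = []
    states = []
    t_start = 0.0
    for k in range(path.n_segments):
        ts = np.arange(0.0, path.dwells[k], dt)
        seg = _core.integrate_dense(p.model_id, q, path.amplitudes[k],
                                    sw[k, 0], sw[k, 1], ts, _RTOL, _ATOL)
        times.append(t_start + ts)
        states.append(seg)
        t_start += path.dwells[k]
    return Trajectory(times=t0 + np.concatenate(times),
                      states=np.vstack(states), path=path,
                      switch_states=sw, params=p,
                      extinct_segment=int(ext_seg),
                      t_extinct=float(t_ext) + (t0 if t_ext >= 0 else 0.0))


@dataclass(frozen=True)
class TippingEvent:
    """One collapse from predator-prey oscillations to extinction.

    t1        tipping time: the causal switch time (yr)
    xb        state at the causal switch
    phase_xb  phase of xb w.r.t. e3(r_pre)
    r_pre     amplitude in force before the causal switch
    r_post    amplitude after it
    klass     'B' (dangerous-bifurcation crossing) or 'P' (phase tipping)
    run       index of the Monte-Carlo run, if any
    """

    t1: float
    xb: np.ndarray
    phase_xb: float
    r_pre: float
    r_post: float
    klass: str
    run: int | None = None


def _membership_code(p: ModelParams, r: float, x,
                     t_settle: float = T_SETTLE) -> int:
    e0 = extinction_state(p)
    return int(_core.classify_frozen(
        p.model_id, p.to_array(), r, float(x[0]), float(x[1]),
        e0[0], e0[1], np.empty((0, 2)), 0.0, t_settle, _RTOL, _ATOL,
        20, 0.0))


def _event_from_switch_states(p: ModelParams, path: ClimatePath,
                              sw: np.ndarray, ext_seg: int,
                              rh: float | None,
                              t_settle: float = T_SETTLE,
                              run: int | None = None) -> TippingEvent:
    """Backtrack from the extinction segment to the causal switch."""
    switch_times = path.switch_times
    k = ext_seg
    # state at the start of ext_seg necessarily leads to extinction;
    # walk back while earlier switch states are also doomed under their
    # own frozen amplitude
    while k - 1 >= 0:
        code = _membership_code(p, path.amplitudes[k - 1], sw[k - 1],
                                t_settle)
        if code != _core.EXTINCT:
            break
        k -= 1
    xb = sw[k].copy()
    r_post = float(path.amplitudes[k])
    r_pre = float(path.amplitudes[k - 1]) if k > 0 else r_post
    anchor = coexistence_equilibrium(p.with_r(r_pre))
    phase = float(phase_of(xb, anchor))
    klass = classify_event_amplitudes(r_post, rh)
    return TippingEvent(t1=float(switch_times[k]), xb=xb, phase_xb=phase,
                        r_pre=r_pre, r_post=r_post, klass=klass, run=run)


def classify_event_amplitudes(r_post: float, rh: float | None) -> str:
    """'B' iff the post-switch amplitude crosses the dangerous
    heteroclinic level; 'P' otherwise (always, when rh is None as in
    the May model)."""
    return "B" if (rh is not None and r_post > rh) else "P"


def classify_event(ev: TippingEvent, rh: float | None) -> str:
    return classify_event_amplitudes(ev.r_post, rh)


def detect_tipping(p: ModelParams, path: ClimatePath, x0,
                   rh: float | None = None,
                   t_settle: float = T_SETTLE) -> TippingEvent | None:
    """Run the switching system and locate the tipping event, if any.

    Returns None when the trajectory never converges to the extinction
    state within the path horizon.
    """
    sw, ext_seg, t_ext, *_ = _run_switching(p, path, x0)
    if ext_seg < 0:
        return None
    return _event_from_switch_states(p, path, sw, int(ext_seg), rh,
                                     t_settle)


@dataclass(frozen=True)
class RescueEvent:
    """An excursion out of the cycle's basin that a later switch undoes."""

    start_segment: int
    end_segment: int
    t_start: float
    t_end: float


def detect_rescue(p: ModelParams, path: ClimatePath, x0,
                  t_settle: float = T_SETTLE) -> list[RescueEvent]:
    """Rescue events of one switching run.

    A rescue is a maximal run of switches whose states are outside the
    basin of the frozen cycle, followed by a switch whose state is back
    inside, without the trajectory having converged to extinction in
    between.  Requires a membership verdict at every switch, so this is
    considerably more expensive than ``detect_tipping``.
    """
    sw, ext_seg, t_ext, *_ = _run_switching(p, path, x0)
    n = path.n_segments if ext_seg < 0 else int(ext_seg) + 1
    codes = np.array([_membership_code(p, path.amplitudes[k], sw[k],
                                       t_settle) for k in range(n)])
    outside = codes == _core.EXTINCT
    times = path.switch_times
    rescues = []
    k = 0
    while k < n:
        if outside[k]:
            j = k
            while j < n and outside[j]:
                j += 1
            if j < n:  # re-entered the basin: rescued
                rescues.append(RescueEvent(start_segment=k,
                                           end_segment=j,
                                           t_start=float(times[k]),
                                           t_end=float(times[j])))
            k = j
        else:
            k += 1
    return rescues


def single_switch_tips(p: ModelParams, r1: float, r2: float, phase: float,
                       cycle1: LimitCycle | None = None,
                       cycle2: LimitCycle | None = None,
                       t_max: float = 500.0) -> bool | None:
    """Does a single switch r1 -> r2 applied at the given cycle phase tip?

    Starts exactly on Gamma(r1) at the given phase, freezes r = r2 and
    integrates.  True on convergence to extinction, False on
    convergence back to Gamma(r2), None if undecided within t_max
    (reported, never guessed).
    """
    if cycle1 is None:
        cycle1 = find_limit_cycle(p.with_r(r1))
        if cycle1 is None:
            raise ValueError(f"no cycle at r1={r1}")
    if cycle2 is None:
        cycle2 = find_limit_cycle(p.with_r(r2), n_samples=800)
        if cycle2 is None:
            raise ValueError(f"no cycle at r2={r2}")
    from .basins import in_basin
    verdict = in_basin(cycle1.state_at_phase(phase), p.with_r(r2),
                       cycle=cycle2, t_max=t_max)
    if verdict == "boundary-undecided":
        return None
    return verdict == "extinction"


@dataclass
class MonteCarloResult:
    """Ensemble of tipping experiments under random climate forcing."""

    events: list[TippingEvent]
    n_runs: int
    n_no_tip: int
    spec: ClimateSpec
    seed: int
    rh: float | None

    @property
    def n_events(self) -> int:
        return len(self.events)

    def counts(self) -> dict[str, int]:
        out = {"B": 0, "P": 0}
        for ev in self.events:
            out[ev.klass] += 1
        return out

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "run": [ev.run for ev in self.events],
            "t1": [ev.t1 for ev in self.events],
            "N_b": [ev.xb[0] for ev in self.events],
            "P_b": [ev.xb[1] for ev in self.events],
            "phase": [ev.phase_xb for ev in self.events],
            "r_pre": [ev.r_pre for ev in self.events],
            "r_post": [ev.r_post for ev in self.events],
            "class": [ev.klass for ev in self.events],
        })


def monte_carlo(p: ModelParams, spec: ClimateSpec, x0, n_events: int,
                seed: int, rh: float | None = None,
                t_settle: float = T_SETTLE) -> MonteCarloResult:
    """Collect tipping events under independent forcing realizations.

    Each run draws a fresh climate path from a per-run RNG stream
    spawned off the master seed (reproducible and order-independent),
    starts at x0 and integrates until collapse or the spec horizon.
    Runs that survive the horizon are counted separately and replaced
    by fresh runs, never silently dropped.
    """
    ss = np.random.SeedSequence(seed)
    events: list[TippingEvent] = []
    n_runs = 0
    n_no_tip = 0
    while len(events) < n_events:
        child = ss.spawn(1)[0]
        rng = np.random.default_rng(child)
        path = generate_path(spec, rng=rng)
        n_runs += 1
        sw, ext_seg, t_ext, *_ = _run_switching(p, path, x0)
        if ext_seg < 0:
            n_no_tip += 1
            continue
        events.append(_event_from_switch_states(
            p, path, sw, int(ext_seg), rh, t_settle, run=n_runs - 1))
    return MonteCarloResult(events=events, n_runs=n_runs,
                            n_no_tip=n_no_tip, spec=spec, seed=seed,
                            rh=rh)
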