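"""Attracting predator-prey limit cycles, their phase and invariant measure.

Phase is defined through a polar coordinate system anchored at the
coexistence equilibrium e3(r), with the predator axis stretched by 1e3
so that prey and predator excursions contribute comparably:

    phi = atan2(1e3 * (P - P3), N - N3)  in [0, 2*pi).

The cycle makes a simple counter-clockwise rotation about e3(r), so this
assigns a unique, strictly increasing phase along the cycle and extends
to oscillatory states in a neighbourhood of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _core
from .models import (ModelParams, coexistence_equilibrium,
                     extinction_state)

__all__ = [
    "LimitCycle",
    "InvariantMeasure",
    "phase_of",
    "find_limit_cycle",
    "cycle_exists",
    "cycle_interval",
    "invariant_measure",
]

PHASE_SCALE = _core.PHASE_SCALE


def phase_of(x, anchor, scale: float = PHASE_SCALE):
    """Phase in [0, 2*pi) of state(s) ``x`` about ``anchor`` = e3(r).

    Accepts a single state (length-2) or an (n, 2) array.  Raises if a
    state coincides with the anchor, where phase is undefined.
    """
    x = np.asarray(x, dtype=float)
    anchor = np.asarray(anchor, dtype=float)
    dN = x[..., 0] - anchor[0]
    dP = scale * (x[..., 1] - anchor[1])
    if np.any((dN == 0.0) & (dP == 0.0)):
        raise ValueError("phase undefined at the anchor equilibrium")
    return np.mod(np.arctan2(dP, dN), 2.0 * np.pi)


@dataclass(frozen=True)
class LimitCycle:
    """One sampled period of an attracting predator-prey cycle Gamma(r).

    samples  (n, 2) states at equal time steps over one period; the
             first sample lies on the Poincare ray {phase = 0, N > N3}
             and samples[-1] does NOT repeat samples[0]
    period   T in years
    anchor   e3(r) used for the phase definition
    r        the frozen climate input the cycle belongs to
    """

    samples: np.ndarray
    period: float
    anchor: np.ndarray
    r: float
    times: np.ndarray = field(repr=False, default=None)

    @property
    def phases(self) -> np.ndarray:
        return phase_of(self.samples, self.anchor)

    def state_at_phase(self, phi: float) -> np.ndarray:
        """Cycle point at the given phase (linear interpolation).

        Uses the monotone unwrapped phase along the time
        parameterization.
        """
        phi = float(np.mod(phi, 2.0 * np.pi))
        ph = np.unwrap(self.phases)
        idx = np.searchsorted(ph, phi)
        if idx == 0 or idx >= len(ph):
            # wrap-around segment between the last and first sample
            a, b = self.samples[-1], self.samples[0]
            pa, pb = ph[-1], ph[0] + 2.0 * np.pi
            phi_w = phi if phi >= pa else phi + 2.0 * np.pi
        else:
            a, b = self.samples[idx - 1], self.samples[idx]
            pa, pb = ph[idx - 1], ph[idx]
            phi_w = phi
        w = 0.0 if pb == pa else (phi_w - pa) / (pb - pa)
        return a + w * (b - a)

    def bounding_box(self) -> tuple[float, float, float, float]:
        return (float(self.samples[:, 0].min()),
                float(self.samples[:, 0].max()),
                float(self.samples[:, 1].min()),
                float(self.samples[:, 1].max()))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "t": self.times,
            "N": self.samples[:, 0],
            "P": self.samples[:, 1],
            "phase": self.phases,
        })


# tunables for the Poincare-return cycle hunt
_RETURN_TOL = 1e-9      # state-space convergence of successive returns
_T_CAP = 5000.0         # years before giving up
_PERTURB = 1e-5         # initial radial offset from e3 along +N
_GROWTH_CYCLE = 5.0     # section radius grew: an attracting cycle exists
_GROWTH_EQ = 0.5        # section radius shrank: e3 attracts, no cycle


_HUNT_RTOL = 1e-10      # tight tolerances keep the numerical Poincare map
_HUNT_ATOL = 1e-13      # reproducible below the 1e-9 return tolerance


def _cycle_hunt(p: ModelParams, rtol: float, atol: float):
    anchor = coexistence_equilibrium(p)
    e0 = extinction_state(p)
    d0 = _PERTURB * max(1.0, anchor[0])
    return anchor, _core.find_cycle(
        p.model_id, p.to_array(), p.r, anchor[0], anchor[1], d0,
        e0[0], e0[1], _RETURN_TOL, _T_CAP, rtol, atol), d0


def cycle_exists(p: ModelParams, rtol: float = _HUNT_RTOL,
                 atol: float = _HUNT_ATOL) -> bool:
    """Does the frozen model at p.r have an attracting limit cycle?

    Integrates from a tiny perturbation of e3(r).  Convergent Poincare
    returns at finite radius mean a cycle; spiralling into e3 or
    reaching the extinction state means none.  If returns have not
    converged within the time cap (slow dynamics near onset), the trend
    of the section radius decides; a truly ambiguous trend falls back
    on the sign of the e3 eigenvalue real part, which changes exactly
    at the oscillatory onset.
    """
    try:
        anchor, res, d0 = _cycle_hunt(p, rtol, atol)
    except ValueError:
        return False
    status, _, _, rad_first, rad_last, n_cross, _ = res
    if status == _core.CYCLE_FOUND:
        return True
    if status in (_core.CYCLE_SPIRAL_IN, _core.CYCLE_EXTINCT):
        return False
    if n_cross >= 2:
        if rad_last > _GROWTH_CYCLE * d0:
            return True
        if rad_last < _GROWTH_EQ * d0:
            return False
    from .models import jacobian
    lam = np.linalg.eigvals(jacobian(anchor, p))
    return float(lam.real.max()) > 0.0


def find_limit_cycle(p: ModelParams, n_samples: int = 2000,
                     rtol: float = _HUNT_RTOL, atol: float = _HUNT_ATOL
                     ) -> LimitCycle | None:
    """Locate Gamma(r) for the frozen model, or None if it does not exist.

    Integrates from a perturbation of e3(r) until successive returns to
    the Poincare ray {phase = 0, N > N3} agree to 1e-9, then samples one
    period at n_samples equal time steps starting from the return point.
    """
    anchor, res, _ = _cycle_hunt(p, rtol, atol)
    status, period, Nc, rad_first, rad_last, n_cross, _ = res
    if status != _core.CYCLE_FOUND:
        if status == _core.CYCLE_UNRESOLVED and cycle_exists(p, rtol, atol):
            raise RuntimeError(
                f"attracting cycle at r={p.r} did not converge to "
                f"return tolerance {_RETURN_TOL} within {_T_CAP} yr; "
                "the cycle is only weakly attracting here")
        return None
    ts = np.linspace(0.0, period, n_samples, endpoint=False)
    samples = _core.integrate_dense(p.model_id, p.to_array(), p.r,
                                    Nc, anchor[1], ts, rtol, atol)
    return LimitCycle(samples=samples, period=period, anchor=anchor,
                      r=p.r, times=ts)


def cycle_interval(p: ModelParams, r_range: tuple[float, float],
                   resolution: float = 1e-3) -> tuple[float, float]:
    """(r_min, r_max) of the attracting-cycle existence interval.

    Bisects ``cycle_exists`` against both ends of ``r_range``, which
    must bracket the interval (no cycle at either end, a cycle
    somewhere inside).  For the RMA model the upper endpoint is the
    heteroclinic value r_h at which predator depletion joins the cycle.
    """
    r_lo, r_hi = map(float, r_range)
    probes = np.linspace(r_lo, r_hi, 9)[1:-1]
    inside = None
    for rp in probes:
        if cycle_exists(p.with_r(rp)):
            inside = float(rp)
            break
    if inside is None:
        raise ValueError(f"no attracting cycle found for r in {r_range}")
    if cycle_exists(p.with_r(r_lo)) or cycle_exists(p.with_r(r_hi)):
        raise ValueError(f"r_range {r_range} does not bracket the "
                         "cycle-existence interval")

    def bisect(a: float, b: float) -> float:
        # invariant: cycle exists at b, not at a
        while abs(b - a) > resolution:
            m = 0.5 * (a + b)
            if cycle_exists(p.with_r(m)):
                b = m
            else:
                a = m
        return 0.5 * (a + b)

    return bisect(r_lo, inside), bisect(r_hi, inside)


@dataclass(frozen=True)
class InvariantMeasure:
    """Normalized time-fraction of the cycle per phase bin."""

    bin_edges: np.ndarray
    masses: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def invariant_measure(cycle: LimitCycle, n_bins: int = 64
                      ) -> InvariantMeasure:
    """Invariant measure of Gamma(r) on [0, 2*pi) phase bins.

    The mass of a bin is the fraction of the period the cycle spends at
    phases inside the bin; with equal-time samples this is a normalized
    histogram of sample phases.  Phases where the motion is slow carry
    large mass and are therefore the likely phases of bifurcation-driven
    tipping.
    """
    if cycle.samples.shape[0] == 0:
        raise ValueError("empty cycle")
    edges = np.linspace(0.0, 2.0 * np.pi, n_bins + 1)
    counts, _ = np.histogram(cycle.phases, bins=edges)
    masses = counts / counts.sum()
    return InvariantMeasure(bin_edges=edges, masses=masses)
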