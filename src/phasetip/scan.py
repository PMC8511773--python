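"""Brute-force one- and two-parameter bifurcation structure.

Only the boundaries that matter for phase tipping are reproduced, by
bisection and grid scans rather than numerical continuation: the Hopf
onset of oscillatory coexistence, the dangerous heteroclinic value r_h
at which the RMA cycle is destroyed (predator depletion joins the
cycle), and the four-region classification of the frozen models by
their attractor inventory.
"""

from __future__ import annotations

import numpy as np

from .cycles import cycle_exists
from .models import (ModelParams, RMAParams, coexistence_equilibrium,
                     equilibria, jacobian)

__all__ = ["hopf_r", "heteroclinic_rh", "classify_region"]


def _re_lambda_e3(p: ModelParams) -> float:
    lam = np.linalg.eigvals(jacobian(coexistence_equilibrium(p), p))
    return float(lam.real.max())


def hopf_r(p: ModelParams, bracket: tuple[float, float],
           resolution: float = 1e-4) -> float:
    """r at which e3 loses stability (supercritical Hopf; the onset of
    oscillatory coexistence, the 'paradox of enrichment').

    Bisects the sign of the largest eigenvalue real part of the
    Jacobian at e3(r) over ``bracket``.
    """
    lo, hi = map(float, bracket)
    flo, fhi = _re_lambda_e3(p.with_r(lo)), _re_lambda_e3(p.with_r(hi))
    if flo * fhi > 0:
        raise ValueError(f"no eigenvalue sign change on {bracket}")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if _re_lambda_e3(p.with_r(mid)) * flo > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def heteroclinic_rh(p: RMAParams, bracket: tuple[float, float] = (2.3, 3.0),
                    resolution: float = 1e-3) -> float:
    """The dangerous heteroclinic value r_h of the RMA cycle.

    Bisects on attracting-cycle existence: below r_h the cycle exists,
    above it the only attractor is extinction.  As r -> r_h the cycle's
    minimum predator density approaches zero and its period grows.
    """
    if not isinstance(p, RMAParams):
        raise TypeError("the heteroclinic cycle destruction is specific "
                        "to the RMA model")
    lo, hi = map(float, bracket)
    if not cycle_exists(p.with_r(lo)) or cycle_exists(p.with_r(hi)):
        raise ValueError(f"bracket {bracket} does not span cycle "
                         "existence -> nonexistence")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if cycle_exists(p.with_r(mid)):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


REGION_OSCILLATORY = "oscillatory-coexistence-or-extinction"
REGION_STATIONARY = "stationary-coexistence-or-extinction"
REGION_PREY_ONLY = "prey-only-or-extinction"
REGION_EXTINCTION = "extinction-only"


def classify_region(p: ModelParams) -> str:
    """Which of the four ecologically relevant regimes p falls in.

    The attractor inventory combines equilibrium stability with the
    forward-integration cycle-existence probe.  The extinction state is
    an attractor everywhere; the label records what coexists with it.
    Ambiguous inventories (e.g. both a stable e3 and an attracting
    cycle) raise instead of guessing.
    """
    eqs = {eq.label: eq for eq in equilibria(p)}
    if eqs["e0"].stability != "attractor":
        raise RuntimeError(f"extinction state unexpectedly non-attracting "
                           f"at r={p.r}")
    has_cycle = False
    e3_stable = "e3" in eqs and eqs["e3"].stability == "attractor"
    if "e3" in eqs and not e3_stable:
        has_cycle = cycle_exists(p)
    if has_cycle and e3_stable:
        raise RuntimeError("ambiguous inventory: stable e3 and a cycle")
    if has_cycle:
        return REGION_OSCILLATORY
    if e3_stable:
        return REGION_STATIONARY
    if eqs["e1"].stability == "attractor":
        return REGION_PREY_ONLY
    return REGION_EXTINCTION
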