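"""Compiled integration kernels for the planar predator-prey flows.

Everything here operates on a flat parameter array ``q`` plus a model flag
(0 = Rosenzweig-MacArthur, 1 = May) so that a single Dormand-Prince 5(4)
stepper serves the whole package: frozen-system classification, limit-cycle
location via Poincare returns, dense trajectory output, piecewise-constant
switching simulations and backward-time manifold growing.

Parameter array layout (see :mod:`phasetip.models`):

    q = [c, alpha, beta, mu, nu, a5, a6, a7]

with ``a5, a6, a7 = chi, delta, 0`` for RMA and ``s, q, eps`` for May.

State distances mix prey and predator densities, which differ by three
orders of magnitude; wherever a metric matters we use the scaled metric
``hypot(dN, 1e3 * dP)`` consistent with the phase definition.
"""

import numpy as np
from numba import njit

#: predator weight in the scaled state metric / phase definition
PHASE_SCALE = 1.0e3

# Dormand-Prince 5(4) tableau
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (19372.0 / 6561.0, -25360.0 / 2187.0,
                          64448.0 / 6561.0, -212.0 / 729.0)
_A61, _A62, _A63, _A64, _A65 = (9017.0 / 3168.0, -355.0 / 33.0,
                                46732.0 / 5247.0, 49.0 / 176.0,
                                -5103.0 / 18656.0)
_B1, _B3, _B4, _B5, _B6 = (35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0,
                           -2187.0 / 6784.0, 11.0 / 84.0)
_E1, _E3, _E4, _E5, _E6, _E7 = (71.0 / 57600.0, -71.0 / 16695.0,
                                71.0 / 1920.0, -17253.0 / 339200.0,
                                22.0 / 525.0, -1.0 / 40.0)


@njit(cache=True, inline="always")
def _rhs(model, q, r, N, P):
    growth = N * (r - q[0] * N) * (N - q[3]) / (q[4] + N)
    pred = q[1] * N * P / (q[2] + N)
    dN = growth - pred
    if model == 0:
        dP = q[5] * pred - q[6] * P
    else:
        dP = q[5] * P * (1.0 - q[6] * P / (N + q[7]))
    return dN, dP


@njit(cache=True, inline="always")
def _dp_step(model, q, r, N, P, h, sgn):
    """One Dormand-Prince trial step of size h (sgn=-1 flips time)."""
    k1N, k1P = _rhs(model, q, r, N, P)
    k1N *= sgn
    k1P *= sgn
    k2N, k2P = _rhs(model, q, r, N + h * _A21 * k1N, P + h * _A21 * k1P)
    k2N *= sgn
    k2P *= sgn
    k3N, k3P = _rhs(model, q, r, N + h * (_A31 * k1N + _A32 * k2N),
                    P + h * (_A31 * k1P + _A32 * k2P))
    k3N *= sgn
    k3P *= sgn
    k4N, k4P = _rhs(model, q, r,
                    N + h * (_A41 * k1N + _A42 * k2N + _A43 * k3N),
                    P + h * (_A41 * k1P + _A42 * k2P + _A43 * k3P))
    k4N *= sgn
    k4P *= sgn
    k5N, k5P = _rhs(model, q, r,
                    N + h * (_A51 * k1N + _A52 * k2N + _A53 * k3N + _A54 * k4N),
                    P + h * (_A51 * k1P + _A52 * k2P + _A53 * k3P + _A54 * k4P))
    k5N *= sgn
    k5P *= sgn
    k6N, k6P = _rhs(model, q, r,
                    N + h * (_A61 * k1N + _A62 * k2N + _A63 * k3N
                             + _A64 * k4N + _A65 * k5N),
                    P + h * (_A61 * k1P + _A62 * k2P + _A63 * k3P
                             + _A64 * k4P + _A65 * k5P))
    k6N *= sgn
    k6P *= sgn
    Nn = N + h * (_B1 * k1N + _B3 * k3N + _B4 * k4N + _B5 * k5N + _B6 * k6N)
    Pn = P + h * (_B1 * k1P + _B3 * k3P + _B4 * k4P + _B5 * k5P + _B6 * k6P)
    k7N, k7P = _rhs(model, q, r, Nn, Pn)
    k7N *= sgn
    k7P *= sgn
    errN = h * (_E1 * k1N + _E3 * k3N + _E4 * k4N + _E5 * k5N
                + _E6 * k6N + _E7 * k7N)
    errP = h * (_E1 * k1P + _E3 * k3P + _E4 * k4P + _E5 * k5P
                + _E6 * k6P + _E7 * k7P)
    return Nn, Pn, errN, errP


@njit(cache=True, inline="always")
def _err_norm(N, P, Nn, Pn, errN, errP, rtol, atol):
    sN = atol + rtol * max(abs(N), abs(Nn))
    sP = atol + rtol * max(abs(P), abs(Pn))
    return np.sqrt(0.5 * ((errN / sN) ** 2 + (errP / sP) ** 2))


@njit(cache=True, inline="always")
def _clip_tiny_negative(v):
    # the flow preserves positivity; only round-off can push a state
    # marginally negative
    if v < 0.0 and v > -1.0e-9:
        return 0.0
    return v


@njit(cache=True)
def integrate_to(model, q, r, N, P, t_span, rtol, atol, sgn):
    """Advance the frozen system by t_span (>0); returns final (N, P)."""
    t = 0.0
    h = 1.0e-3
    while t < t_span:
        if h > t_span - t:
            h = t_span - t
        Nn, Pn, errN, errP = _dp_step(model, q, r, N, P, h, sgn)
        en = _err_norm(N, P, Nn, Pn, errN, errP, rtol, atol)
        if en <= 1.0 and Nn > -1.0e-9 and Pn > -1.0e-9:
            t += h
            N = _clip_tiny_negative(Nn)
            P = _clip_tiny_negative(Pn)
            fac = 5.0 if en == 0.0 else min(5.0, max(0.2, 0.9 * en ** -0.2))
            h *= fac
        else:
            h *= 0.5 if en <= 1.0 else max(0.2, 0.9 * en ** -0.2)
            if h < 1.0e-12:
                # cannot resolve the step; bail out with the current state
                return N, P
    return N, P


@njit(cache=True)
def integrate_dense(model, q, r, N, P, ts, rtol, atol):
    """States of the frozen system at the strictly increasing times ts.

    ts[0] is the initial time of (N, P); output row 0 is the input state.
    """
    out = np.empty((ts.shape[0], 2))
    out[0, 0] = N
    out[0, 1] = P
    for i in range(1, ts.shape[0]):
        N, P = integrate_to(model, q, r, N, P, ts[i] - ts[i - 1],
                            rtol, atol, 1.0)
        out[i, 0] = N
        out[i, 1] = P
    return out


# status codes for find_cycle
CYCLE_FOUND = 0
CYCLE_SPIRAL_IN = 1
CYCLE_EXTINCT = 2
CYCLE_UNRESOLVED = 3


@njit(cache=True)
def find_cycle(model, q, r, N3, P3, d0, e0N, e0P, tol_ret, t_max, rtol, atol):
    """Hunt the attracting cycle from a small radial perturbation of e3.

    Poincare section: the ray {P = P3, N > N3} crossed upward (the cycle
    rotates counter-clockwise).  Returns

        (status, period, NcrossN, rad_first, rad_last, n_cross, t_conv)

    where ``rad_*`` are the section radii N_cross - N3 of the first/last
    returns; they let the caller discriminate slow outward spiralling
    (a cycle is forming) from slow inward spiralling near a Hopf point
    when tol_ret is not reached within t_max.
    """
    N = N3 + d0
    P = P3
    t = 0.0
    h = 1.0e-3
    prevN, prevP = N, P
    last_cross = -1.0
    prev_cross_t = -1.0
    rad_first = -1.0
    rad_last = -1.0
    n_cross = 0
    while t < t_max:
        if h > t_max - t:
            h = t_max - t
        Nn, Pn, errN, errP = _dp_step(model, q, r, N, P, h, 1.0)
        en = _err_norm(N, P, Nn, Pn, errN, errP, rtol, atol)
        if en <= 1.0 and Nn > -1.0e-9 and Pn > -1.0e-9:
            t += h
            hu = h
            prevN, prevP = N, P
            N = _clip_tiny_negative(Nn)
            P = _clip_tiny_negative(Pn)
            fac = 5.0 if en == 0.0 else min(5.0, max(0.2, 0.9 * en ** -0.2))
            h *= fac
            # extinction-state check (plain Euclidean distance)
            if np.hypot(N - e0N, P - e0P) < 1.0e-4:
                return CYCLE_EXTINCT, 0.0, 0.0, rad_first, rad_last, \
                    n_cross, t
            # upward crossing of P = P3 with N > N3: refine the crossing
            # by bisection on a single trial step from the step start
            # (one fifth-order step over a sub-interval is far more
            # accurate than linear interpolation across the full step)
            if prevP < P3 and P >= P3 and P > prevP:
                lo_s = 0.0
                hi_s = hu
                Nc = N
                for _ in range(60):
                    mid = 0.5 * (lo_s + hi_s)
                    Nm, Pm, _, _ = _dp_step(model, q, r, prevN, prevP,
                                            mid, 1.0)
                    if Pm >= P3:
                        hi_s = mid
                        Nc = Nm
                    else:
                        lo_s = mid
                    if hi_s - lo_s < 1.0e-14:
                        break
                tc = t - hu + hi_s
                if Nc > N3:
                    rad = Nc - N3
                    if n_cross == 0:
                        rad_first = rad
                    rad_last = rad
                    n_cross += 1
                    if last_cross >= 0.0:
                        if abs(Nc - last_cross) < tol_ret:
                            period = tc - prev_cross_t
                            if rad < 1.0e-3:
                                return CYCLE_SPIRAL_IN, period, Nc, \
                                    rad_first, rad_last, n_cross, t
                            return CYCLE_FOUND, period, Nc, rad_first, \
                                rad_last, n_cross, t
                    prev_cross_t = tc
                    last_cross = Nc
        else:
            h *= 0.5 if en <= 1.0 else max(0.2, 0.9 * en ** -0.2)
            if h < 1.0e-12:
                break
    return CYCLE_UNRESOLVED, 0.0, 0.0, rad_first, rad_last, n_cross, t


# membership codes
IN_BASIN = 0
EXTINCT = 1
UNDECIDED = 2


@njit(cache=True)
def classify_frozen(model, q, r, N, P, e0N, e0P, cyc, tol_cyc, t_max,
                    rtol, atol, check_every, t_near):
    """Forward-integrate the frozen system and classify the fate of (N, P).

    EXTINCT as soon as the prey density falls below the Allee density mu
    (below mu the prey decline is monotone in both models, so extinction
    is certain) or the state enters the 1e-4 ball around the extinction
    attractor.  If ``cyc`` (n x 2 samples of the attracting cycle) is
    non-empty, IN_BASIN once the state has remained within the scaled
    distance tol_cyc of the cycle for a continuous stretch of t_near
    years -- transient proximity is not enough, because doomed
    trajectories squeeze past the cycle where the basin boundary runs
    close to it.  Hitting t_max without either verdict returns UNDECIDED.
    """
    t = 0.0
    h = 1.0e-3
    nacc = 0
    m = cyc.shape[0]
    mu_exit = q[3] * (1.0 - 1.0e-6)
    near_since = -1.0
    while t < t_max:
        if h > t_max - t:
            h = t_max - t
        Nn, Pn, errN, errP = _dp_step(model, q, r, N, P, h, 1.0)
        en = _err_norm(N, P, Nn, Pn, errN, errP, rtol, atol)
        if en <= 1.0 and Nn > -1.0e-9 and Pn > -1.0e-9:
            t += h
            N = _clip_tiny_negative(Nn)
            P = _clip_tiny_negative(Pn)
            fac = 5.0 if en == 0.0 else min(5.0, max(0.2, 0.9 * en ** -0.2))
            h *= fac
            nacc += 1
            if N < mu_exit or np.hypot(N - e0N, P - e0P) < 1.0e-4:
                return EXTINCT
            if m > 0 and nacc % check_every == 0:
                dmin = 1.0e300
                for j in range(m):
                    d = np.hypot(N - cyc[j, 0],
                                 PHASE_SCALE * (P - cyc[j, 1]))
                    if d < dmin:
                        dmin = d
                if dmin < tol_cyc:
                    if near_since < 0.0:
                        near_since = t
                    elif t - near_since >= t_near:
                        return IN_BASIN
                else:
                    near_since = -1.0
        else:
            h *= 0.5 if en <= 1.0 else max(0.2, 0.9 * en ** -0.2)
            if h < 1.0e-12:
                return UNDECIDED
    return UNDECIDED


@njit(cache=True)
def classify_frozen_many(model, q, r, pts, e0N, e0P, cyc, tol_cyc, t_max,
                         rtol, atol, check_every, t_near):
    out = np.empty(pts.shape[0], dtype=np.int64)
    for i in range(pts.shape[0]):
        out[i] = classify_frozen(model, q, r, pts[i, 0], pts[i, 1],
                                 e0N, e0P, cyc, tol_cyc, t_max,
                                 rtol, atol, check_every, t_near)
    return out


@njit(cache=True)
def simulate_switching(model, q, durs, amps, N, P, e0N, e0P, rtol, atol):
    """Piecewise-constant switching run.

    durs/amps: dwell lengths (years) and r amplitudes per segment.  The
    state is passed continuously across switches.  Stops once the state
    has entered the 1e-4 ball of the extinction attractor and is still
    inside it at the end of that segment ("sustained" convergence).

    Returns (switch_states, extinct_seg, t_extinct, Nf, Pf, t_final):
    switch_states[k] is the state at the START of segment k;
    extinct_seg = -1 if the run survives the whole path.
    """
    nseg = durs.shape[0]
    switch_states = np.empty((nseg, 2))
    t = 0.0
    for k in range(nseg):
        switch_states[k, 0] = N
        switch_states[k, 1] = P
        r = amps[k]
        seg_end = t + durs[k]
        t_hit = -1.0
        h = 1.0e-3
        tt = t
        while tt < seg_end:
            if h > seg_end - tt:
                h = seg_end - tt
            Nn, Pn, errN, errP = _dp_step(model, q, r, N, P, h, 1.0)
            en = _err_norm(N, P, Nn, Pn, errN, errP, rtol, atol)
            if en <= 1.0 and Nn > -1.0e-9 and Pn > -1.0e-9:
                tt += h
                N = _clip_tiny_negative(Nn)
                P = _clip_tiny_negative(Pn)
                fac = 5.0 if en == 0.0 else min(5.0,
                                                max(0.2, 0.9 * en ** -0.2))
                h *= fac
                if t_hit < 0.0 and np.hypot(N - e0N, P - e0P) < 1.0e-4:
                    t_hit = tt
            else:
                h *= 0.5 if en <= 1.0 else max(0.2, 0.9 * en ** -0.2)
                if h < 1.0e-12:
                    break
        t = seg_end
        if t_hit >= 0.0 and np.hypot(N - e0N, P - e0P) < 1.0e-4:
            return switch_states, k, t_hit, N, P, t
    return switch_states, -1, -1.0, N, P, t


@njit(cache=True)
def grow_manifold(model, q, r, N, P, nlo, nhi, plo, phi, t_max, max_pts,
                  rtol, atol):
    """Backward-time orbit from (N, P), recorded at every accepted step.

    Used to grow one branch of the stable manifold of a saddle.  Stops on
    leaving the box [nlo, nhi] x [plo, phi], after t_max of backward time,
    or when max_pts points have been stored.  Returns (points, count).
    """
    pts = np.empty((max_pts, 2))
    pts[0, 0] = N
    pts[0, 1] = P
    n = 1
    t = 0.0
    h = 1.0e-4
    while t < t_max and n < max_pts:
        Nn, Pn, errN, errP = _dp_step(model, q, r, N, P, h, -1.0)
        en = _err_norm(N, P, Nn, Pn, errN, errP, rtol, atol)
        if en <= 1.0:
            t += h
            N, P = Nn, Pn
            pts[n, 0] = N
            pts[n, 1] = P
            n += 1
            fac = 5.0 if en == 0.0 else min(5.0, max(0.2, 0.9 * en ** -0.2))
            h *= fac
            if N < nlo or N > nhi or P < plo or P > phi:
                break
        else:
            h *= max(0.2, 0.9 * en ** -0.2)
            if h < 1.0e-14:
                break
    return pts[:n], n
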