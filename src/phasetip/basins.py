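"""Allee thresholds and (partial) basin instability of predator-prey cycles.

In the bistable "oscillatory coexistence or extinction" regime the basin
boundary of the cycle Gamma(r) is the Allee threshold theta(r): the
stable invariant manifold of a saddle equilibrium (the Allee saddle e2
for the RMA model, the coexistence saddle e4 for the May model).  A drop
in the climate input from r1 to r2 moves the threshold; if part of
Gamma(r1) ends up on the extinction side of theta(r2), exactly those
phases of the cycle tip -- the geometric mechanism of phase tipping.

Two independent membership routes are provided:

* forward integration of the frozen system (``in_basin``), the
  ground-truth route used by the basin-instability classifier, and
* a geometric side-of-threshold test against the theta(r) polyline
  (``AlleeThreshold.classify``), used for the union-of-cycles partition
  and as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _core
from .cycles import LimitCycle, find_limit_cycle, phase_of
from .models import (Equilibrium, ModelParams, coexistence_equilibrium,
                     extinction_state, jacobian, saddle_equilibrium)

__all__ = [
    "AlleeThreshold",
    "BasinInstability",
    "allee_threshold",
    "in_basin",
    "classify_basin_instability",
    "basin_unstable_phases",
    "marginal_r2",
    "bi_region",
    "union_of_cycles",
    "CycleUnion",
]

_W = _core.PHASE_SCALE  # predator weight of the scaled metric


def _scaled(pts: np.ndarray) -> np.ndarray:
    out = np.array(pts, dtype=float, copy=True)
    out[..., 1] *= _W
    return out


def _decimate(poly: np.ndarray, ds: float) -> np.ndarray:
    """Drop polyline points closer than ds (scaled metric) to the last
    kept point; endpoints are always kept."""
    if len(poly) <= 2:
        return poly
    ps = _scaled(poly)
    keep = [0]
    last = ps[0]
    for i in range(1, len(ps) - 1):
        if np.hypot(*(ps[i] - last)) >= ds:
            keep.append(i)
            last = ps[i]
    keep.append(len(ps) - 1)
    return poly[keep]


@dataclass(frozen=True)
class AlleeThreshold:
    """Polyline approximation of the basin boundary theta(r).

    polyline    ordered (n, 2) states; passes through the saddle
    saddle      the anchoring saddle equilibrium es(r)
    r           frozen input value
    box         truncation box (n_lo, n_hi, p_lo, p_hi)
    _extinction shapely polygon (scaled coords) of the extinction side:
                the theta curve closed along the box boundary, chosen as
                the closure that does NOT contain e3(r)
    """

    polyline: np.ndarray
    saddle: Equilibrium
    r: float
    box: tuple
    _extinction: object

    def distance(self, pts) -> np.ndarray:
        """Scaled-metric distance of each point to the theta polyline."""
        import shapely
        from shapely.geometry import LineString
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        line = LineString(_scaled(self.polyline))
        return shapely.distance(line, shapely.points(_scaled(pts)))

    def is_extinction_side(self, pts) -> np.ndarray:
        """True where a point lies on the extinction side of theta(r).

        Points outside the truncation box are resolved by nearest-
        feature side of the closed region (shapely covers test).
        """
        import shapely
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        s = _scaled(pts)
        return shapely.contains_xy(self._extinction, s[:, 0], s[:, 1])

    def classify(self, pts, tol_b: float = 0.02) -> np.ndarray:
        """Geometric membership per point: 'cycle', 'extinction' or
        'boundary' (within scaled distance tol_b of theta)."""
        out = np.where(self.is_extinction_side(pts), "extinction",
                       "cycle").astype(object)
        out[self.distance(pts) < tol_b] = "boundary"
        return out

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"N": self.polyline[:, 0],
                             "P": self.polyline[:, 1]})


def _box_perimeter_path(a: np.ndarray, b: np.ndarray, corners: np.ndarray,
                        direction: int) -> list[np.ndarray]:
    """Points along the box perimeter from a to b (both on/near the
    boundary), walking in the given direction (+1 counter-clockwise)."""

    def station(pt: np.ndarray) -> float:
        # perimeter coordinate of the nearest boundary point
        x0, y0 = corners[0]
        x1, y1 = corners[2]
        w, h = x1 - x0, y1 - y0
        cand = [
            (abs(pt[1] - y0), np.clip(pt[0] - x0, 0, w)),
            (abs(pt[0] - x1), w + np.clip(pt[1] - y0, 0, h)),
            (abs(pt[1] - y1), w + h + np.clip(x1 - pt[0], 0, w)),
            (abs(pt[0] - x0), 2 * w + h + np.clip(y1 - pt[1], 0, h)),
        ]
        return min(cand)[1]

    x0, y0 = corners[0]
    x1, y1 = corners[2]
    w, h = x1 - x0, y1 - y0
    per = 2 * (w + h)
    corner_stations = [0.0, w, w + h, 2 * w + h, per]

    def locate(s: float) -> np.ndarray:
        s = s % per
        if s <= w:
            return np.array([x0 + s, y0])
        if s <= w + h:
            return np.array([x1, y0 + (s - w)])
        if s <= 2 * w + h:
            return np.array([x1 - (s - w - h), y1])
        return np.array([x0, y1 - (s - 2 * w - h)])

    sa, sb = station(a), station(b)
    path = []
    s = sa
    guard = 0
    while guard < 10:
        guard += 1
        # next corner strictly between s and sb in the walk direction
        if direction > 0:
            nxt = min((c for c in corner_stations
                       if (c - s) % per > 1e-12
                       and (c - s) % per < (sb - s) % per),
                      key=lambda c: (c - s) % per, default=None)
        else:
            nxt = min((c for c in corner_stations
                       if (s - c) % per > 1e-12
                       and (s - c) % per < (s - sb) % per),
                      key=lambda c: (s - c) % per, default=None)
        if nxt is None:
            break
        path.append(locate(nxt))
        s = nxt
    return path


def _close_extinction_region(polyline_s: np.ndarray, box_s: tuple,
                             e3_s: np.ndarray):
    """Close the scaled theta curve along the box boundary into a
    polygon; return the closure that does not contain e3 (the
    extinction side)."""
    from shapely.geometry import Point, Polygon

    nlo, nhi, plo, phi = box_s
    corners = np.array([[nlo, plo], [nhi, plo], [nhi, phi], [nlo, phi]])
    a, b = polyline_s[-1], polyline_s[0]  # walk from end back to start
    candidates = []
    for direction in (+1, -1):
        ring = np.vstack([polyline_s,
                          *_box_perimeter_path(a, b, corners, direction),
                          polyline_s[:1]])
        poly = Polygon(ring)
        if not poly.is_valid:
            poly = poly.buffer(0.0)
        candidates.append(poly)
    pt = Point(e3_s)
    inside = [cand.contains(pt) for cand in candidates]
    if inside == [True, False]:
        return candidates[1]
    if inside == [False, True]:
        return candidates[0]
    # fall back to the smaller region not containing e3
    without = [c for c, i in zip(candidates, inside) if not i]
    if without:
        return min(without, key=lambda c: c.area)
    raise RuntimeError("could not orient the Allee threshold closure")


def allee_threshold(p: ModelParams, box=None, offset: float = 1e-6,
                    t_max: float = 200.0, max_pts: int = 400_000,
                    rtol: float = 1e-10, atol: float = 1e-13,
                    ds: float = 0.002) -> AlleeThreshold:
    """Compute theta(r) as the stable manifold of the saddle es(r).

    Both branches are grown by backward-time integration from +-offset
    along the stable eigenvector of the saddle, truncated at the box
    [0, n_hi] x [0, p_hi] (default: 3x the bounding box of Gamma(r),
    generous enough to cover cycles of nearby r values) and decimated
    to a manageable polyline.  For tests against cycles from other
    parameter values pass a box that covers those cycles too.
    """
    sad = saddle_equilibrium(p)
    J = jacobian(sad.location, p)
    lam, vec = np.linalg.eig(J)
    lam = lam.real
    if not (lam.min() < 0 < lam.max()):
        raise ValueError(f"es(r) eigenstructure is not a saddle: {lam}")
    v = vec[:, np.argmin(lam)].real
    v = v / np.hypot(*v)
    if box is None:
        cyc = find_limit_cycle(p, n_samples=800)
        if cyc is None:
            raise ValueError(f"no attracting cycle at r={p.r}; pass an "
                             "explicit truncation box")
        nlo, nhi, plo, phi = cyc.bounding_box()
        box = (0.0, 3.0 * nhi, 0.0, 3.0 * phi)
    nlo, nhi, plo, phi = box
    q = p.to_array()
    branches = []
    for sgn in (+1.0, -1.0):
        x0 = sad.location + sgn * offset * v
        pts, n = _core.grow_manifold(p.model_id, q, p.r, x0[0], x0[1],
                                     nlo - 1e-9, nhi, plo - 1e-9, phi,
                                     t_max, max_pts, rtol, atol)
        branches.append(_decimate(pts, ds))
    # order the branches into one curve through the saddle, running from
    # the low-P end (near the prey axis) outward
    lowP, highP = sorted(branches, key=lambda b: b[-1][1])
    polyline = np.vstack([lowP[::-1], sad.location[None, :], highP])
    e3 = coexistence_equilibrium(p)
    box_s = (nlo, nhi, _W * plo, _W * phi)
    ext = _close_extinction_region(_scaled(polyline), box_s, _scaled(e3))
    return AlleeThreshold(polyline=polyline, saddle=sad, r=p.r,
                          box=tuple(box), _extinction=ext)


def in_basin(x, p: ModelParams, cycle: LimitCycle | None = None,
             t_max: float = 500.0, tol_cyc: float = 0.05,
             rtol: float = 1e-8, atol: float = 1e-10) -> str:
    """Fate of x under the frozen flow: 'cycle', 'extinction' or
    'boundary-undecided'.

    Extinction is certain once the prey density drops below the Allee
    density mu (prey decline is monotone there) or the state enters the
    1e-4 ball of the extinction attractor.  Convergence to the cycle
    requires sustained proximity (scaled distance < tol_cyc over a full
    cycle period) to the sampled Gamma(r) -- doomed trajectories can
    brush past the cycle transiently.  Exhausting t_max is reported as
    'boundary-undecided', never silently classified.
    """
    if cycle is None:
        cycle = find_limit_cycle(p, n_samples=800)
        if cycle is None:
            raise ValueError(f"no attracting cycle at r={p.r}")
    e0 = extinction_state(p)
    x = np.asarray(x, dtype=float)
    code = _core.classify_frozen(p.model_id, p.to_array(), p.r,
                                 float(x[0]), float(x[1]), e0[0], e0[1],
                                 _arc_resample(cycle.samples, 1024),
                                 tol_cyc, t_max, rtol, atol, 20,
                                 1.25 * cycle.period)
    return {_core.IN_BASIN: "cycle", _core.EXTINCT: "extinction",
            _core.UNDECIDED: "boundary-undecided"}[int(code)]


def _subsample(samples: np.ndarray, n: int) -> np.ndarray:
    if len(samples) <= n:
        return np.ascontiguousarray(samples)
    idx = np.linspace(0, len(samples) - 1, n).astype(int)
    return np.ascontiguousarray(samples[idx])


def _arc_resample(samples: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed curve at n points equally spaced in scaled arc
    length.

    Equal-time samples of a predator-prey cycle concentrate where the
    motion is slow; the narrow basin-unstable arcs live in the fast
    prey-crash segment and need arc-length coverage to be resolved.
    """
    s = np.asarray(samples, dtype=float)
    closed = np.vstack([s, s[:1]])
    seg = np.hypot(np.diff(closed[:, 0]),
                   _W * np.diff(closed[:, 1]))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    tgt = np.linspace(0.0, cum[-1], n, endpoint=False)
    idx = np.searchsorted(cum, tgt, side="right") - 1
    idx = np.clip(idx, 0, len(s) - 1)
    denom = np.where(seg[idx] == 0.0, 1.0, seg[idx])
    frac = (tgt - cum[idx]) / denom
    nxt = (idx + 1) % len(s)
    return s[idx] + frac[:, None] * (s[nxt] - s[idx])


def _memberships(p2: ModelParams, pts: np.ndarray,
                 cycle2: LimitCycle | None, t_max: float = 500.0,
                 tol_cyc: float = 0.05, rtol: float = 1e-8,
                 atol: float = 1e-10) -> np.ndarray:
    """Vectorized frozen-system membership codes for pts under p2."""
    e0 = extinction_state(p2)
    cyc = (_arc_resample(cycle2.samples, 1024) if cycle2 is not None
           else np.empty((0, 2)))
    t_near = 1.25 * cycle2.period if cycle2 is not None else 0.0
    return _core.classify_frozen_many(p2.model_id, p2.to_array(), p2.r,
                                      np.ascontiguousarray(pts),
                                      e0[0], e0[1], cyc, tol_cyc, t_max,
                                      rtol, atol, 20, t_near)


@dataclass(frozen=True)
class BasinInstability:
    """Outcome of testing Gamma(p1) against the basin of Gamma(p2).

    klass         'none', 'marginal', 'partial', 'almost_total', 'total'
    out_fraction  fraction of the cycle (by scaled arc length) outside
                  B(Gamma, p2)
    phases        phase of every sampled cycle point (w.r.t. e3(p1)),
                  in time order along the cycle
    outside       boolean mask aligned with phases
    """

    klass: str
    out_fraction: float
    in_fraction: float
    undecided_fraction: float
    phases: np.ndarray
    outside: np.ndarray

    @property
    def arcs(self) -> list[tuple[float, float]]:
        """Maximal basin-unstable phase arcs [(phi_lo, phi_hi), ...].

        Arcs are contiguous runs of outside points along the cycle's
        time order; an arc wrapping 2*pi is reported with
        phi_lo > phi_hi.
        """
        out = self.outside
        if not out.any():
            return []
        if out.all():
            return [(0.0, 2.0 * np.pi)]
        n = len(out)
        # rotate so the run starts inside
        start = int(np.argmin(out))
        rot = np.roll(out, -start)
        arcs = []
        i = 0
        while i < n:
            if rot[i]:
                j = i
                while j < n and rot[j]:
                    j += 1
                lo = self.phases[(start + i) % n]
                hi = self.phases[(start + j - 1) % n]
                arcs.append((float(lo), float(hi)))
                i = j
            else:
                i += 1
        return arcs


def classify_basin_instability(p1: ModelParams, p2: ModelParams,
                               n_samples: int = 2000,
                               n_arc: int = 4000,
                               tangency_frac: float = 0.002,
                               max_undecided: float = 0.01,
                               cycle1: LimitCycle | None = None,
                               cycle2: LimitCycle | None = None,
                               t_max: float = 500.0) -> BasinInstability:
    """Basin-instability class of Gamma(p1) on the path step p1 -> p2.

    Resamples Gamma(p1) at n_arc points equally spaced in scaled arc
    length (equal-time sampling starves the fast prey-crash segment
    where the narrow tangency arcs live) and forward-integrates each
    point under the frozen system at p2.  'none' if every point
    converges back to Gamma(p2); 'total' if none does; 'partial'
    otherwise.  Out- or in-fractions at or below tangency_frac are
    flagged as the indiscernible 'marginal' / 'almost_total' cases
    (closure membership is not computable exactly in floating point).
    Refuses to classify if more than max_undecided of the samples fail
    to resolve.
    """
    if cycle1 is None:
        cycle1 = find_limit_cycle(p1, n_samples=n_samples)
    if cycle1 is None:
        raise ValueError(f"no attracting cycle at p1 (r={p1.r})")
    if cycle2 is None:
        cycle2 = find_limit_cycle(p2, n_samples=800)
    if cycle2 is None:
        raise ValueError(f"no attracting cycle at p2 (r={p2.r})")
    pts = _arc_resample(cycle1.samples, n_arc)
    codes = _memberships(p2, pts, cycle2, t_max=t_max)
    und = float(np.mean(codes == _core.UNDECIDED))
    if und > max_undecided:
        raise RuntimeError(
            f"{und:.1%} of cycle samples undecided under p2 (r={p2.r}); "
            "refusing to classify")
    outside = codes == _core.EXTINCT
    out_frac = float(np.mean(outside))
    in_frac = float(np.mean(codes == _core.IN_BASIN))
    if out_frac == 0.0:
        klass = "none"
    elif in_frac == 0.0:
        klass = "total"
    elif out_frac <= tangency_frac:
        klass = "marginal"
    elif in_frac <= tangency_frac:
        klass = "almost_total"
    else:
        klass = "partial"
    return BasinInstability(klass=klass, out_fraction=out_frac,
                            in_fraction=in_frac, undecided_fraction=und,
                            phases=phase_of(pts, cycle1.anchor),
                            outside=outside)


def basin_unstable_phases(p1: ModelParams, p2: ModelParams,
                          **kwargs) -> list[tuple[float, float]]:
    """Maximal arcs of [0, 2*pi) whose Gamma(p1) points lie outside the
    closure of B(Gamma, p2).  Empty when there is no basin instability."""
    return classify_basin_instability(p1, p2, **kwargs).arcs


def marginal_r2(p: ModelParams, r1: float,
                bracket: tuple[float, float],
                resolution: float = 1e-3,
                n_arc: int = 4000,
                t_max: float = 500.0) -> float:
    """Critical r2 separating 'none' from 'partial' basin instability.

    Bisects the none/partial transition of Gamma(r1) against the frozen
    system at r2 on the decreasing-r path.  bracket = (lo, hi) must
    satisfy: partial at lo, none at hi.
    """
    p1 = p.with_r(r1)
    cycle1 = find_limit_cycle(p1, n_samples=n_arc)
    if cycle1 is None:
        raise ValueError(f"no attracting cycle at r1={r1}")
    pts = _arc_resample(cycle1.samples, n_arc)
    # spread the scan order so an early sample lands in any unstable arc
    order = np.argsort((np.arange(n_arc) * 0.6180339887498949) % 1.0)
    pts = pts[order]

    def unstable(r2: float) -> bool:
        p2 = p.with_r(r2)
        cycle2 = find_limit_cycle(p2, n_samples=800)
        if cycle2 is None:
            raise ValueError(f"no attracting cycle at r2={r2}")
        for lo_i in range(0, n_arc, 256):
            codes = _memberships(p2, pts[lo_i:lo_i + 256], cycle2,
                                 t_max=t_max)
            if np.any(codes == _core.EXTINCT):
                return True
        return False

    lo, hi = map(float, bracket)
    if not unstable(lo) or unstable(hi):
        raise ValueError(f"bracket {bracket} does not span the "
                         "none/partial transition")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if unstable(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bi_region(p1: ModelParams, r_values, second_values,
              second_param: str, n_samples: int = 400) -> np.ndarray:
    """Region-of-basin-instability grid for Gamma(p1).

    For every p2 on the grid (r, second_param) the entry is 1 if
    Gamma(p2) exists and Gamma(p1) is not contained in B(Gamma, p2),
    0 if Gamma(p2) exists and contains Gamma(p1) in its basin, and -1
    (not applicable) where no attracting cycle exists.
    """
    cycle1 = find_limit_cycle(p1, n_samples=n_samples)
    if cycle1 is None:
        raise ValueError("p1 must carry an attracting cycle")
    grid = np.full((len(second_values), len(r_values)), -1, dtype=int)
    for i, sv in enumerate(second_values):
        for j, rv in enumerate(r_values):
            p2 = replace(p1, r=float(rv), **{second_param: float(sv)})
            cyc2 = find_limit_cycle(p2, n_samples=400)
            if cyc2 is None:
                continue
            res = classify_basin_instability(p1, p2, n_samples=n_samples,
                                             cycle1=cycle1, cycle2=cyc2)
            grid[i, j] = 1 if res.out_fraction > 0.0 else 0
    return grid


@dataclass(frozen=True)
class CycleUnion:
    """Union G of the cycle family on a path r in [r2, r1], partitioned
    by membership in the closure of B(Gamma, r2) via the theta(r2)
    side test (the basin-unstable part is where phase tipping can
    start)."""

    rs: np.ndarray
    cycles: list
    unstable_masks: list
    threshold: AlleeThreshold

    def points(self, unstable: bool | None = None) -> np.ndarray:
        rows = []
        for cyc, mask in zip(self.cycles, self.unstable_masks):
            if unstable is None:
                rows.append(cyc.samples)
            else:
                rows.append(cyc.samples[mask == unstable])
        return np.vstack(rows)


def union_of_cycles(p: ModelParams, r2: float, r1: float, n: int = 25,
                    n_samples: int = 500, tol_b: float = 0.0) -> CycleUnion:
    """Sample the cycle family on [r2, r1] and split it by theta(r2).

    Every cycle on the path must exist.  tol_b > 0 treats a band around
    theta(r2) as basin-stable (closure membership).
    """
    rs = np.linspace(r2, r1, n)
    cycles = []
    for rv in rs:
        cyc = find_limit_cycle(p.with_r(float(rv)), n_samples=n_samples)
        if cyc is None:
            raise ValueError(f"path leaves the cycle-existence interval "
                             f"at r={rv}")
        cycles.append(cyc)
    n_hi = max(c.bounding_box()[1] for c in cycles)
    p_hi = max(c.bounding_box()[3] for c in cycles)
    theta = allee_threshold(p.with_r(r2),
                            box=(0.0, 2.0 * n_hi, 0.0, 2.0 * p_hi))
    masks = []
    for cyc in cycles:
        ext = theta.is_extinction_side(cyc.samples)
        if tol_b > 0:
            ext &= theta.distance(cyc.samples) > tol_b
        masks.append(ext)
    return CycleUnion(rs=rs, cycles=cycles, unstable_masks=masks,
                      threshold=theta)
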