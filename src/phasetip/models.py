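"""Autonomous ("frozen") predator-prey vector fields with an Allee effect.

Two planar models are supported, both with a strong Allee effect in the
prey equation and parameterized for the Canada lynx / snowshoe hare
system (densities in animals per hectare, rates per year):

* the Rosenzweig-MacArthur (RMA) model, whose predator dies out
  exponentially at rate ``delta`` without the focal prey, and
* the May (Leslie-Gower) model, whose predator has access to alternative
  prey and persists at the low density ``eps / q`` when the focal prey
  is extinct.

The prey growth rate ``r`` doubles as the climate proxy: the carrying
capacity of the environment is ``r / c``.  The frozen system fixes
``r`` in time; the non-autonomous machinery in :mod:`phasetip.tipping`
switches it between frozen values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "RMAParams",
    "MayParams",
    "Equilibrium",
    "table1",
    "rma_vector_field",
    "may_vector_field",
    "vector_field",
    "jacobian",
    "equilibria",
    "coexistence_equilibrium",
    "extinction_state",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"parameter {name!r} must be strictly positive, "
                             f"got {value!r}")


@dataclass(frozen=True)
class RMAParams:
    """Rosenzweig-MacArthur parameter set.

    r      prey growth rate (1/yr); the time-varying climate input
    c      growth modification (ha/(prey*yr)); carrying capacity is r/c
    alpha  saturation predator kill rate (prey/(pred*yr))
    beta   predator kill half-saturation constant (prey/ha)
    chi    prey-to-predator conversion ratio (pred/prey)
    delta  predator mortality rate (1/yr)
    mu, nu Allee-effect parameters (prey/ha); prey growth is negative
           below the Allee threshold density mu
    """

    r: float
    c: float
    alpha: float
    beta: float
    chi: float
    delta: float
    mu: float
    nu: float

    model_id = 0
    model_name = "rma"

    def __post_init__(self) -> None:
        _require_positive(r=self.r, c=self.c, alpha=self.alpha,
                          beta=self.beta, chi=self.chi, delta=self.delta,
                          mu=self.mu, nu=self.nu)
        if self.chi * self.alpha <= self.delta:
            raise ValueError(
                "chi*alpha must exceed delta for a finite coexistence "
                f"equilibrium (got chi*alpha = {self.chi * self.alpha}, "
                f"delta = {self.delta})")

    def with_r(self, r: float) -> "RMAParams":
        return replace(self, r=r)

    def to_array(self) -> np.ndarray:
        return np.array([self.c, self.alpha, self.beta, self.mu, self.nu,
                         self.chi, self.delta, 0.0])


@dataclass(frozen=True)
class MayParams:
    """May (Leslie-Gower) parameter set.

    Shares r, c, alpha, beta, mu, nu with the RMA model;

    s      low-density predator growth rate (1/yr)
    q      minimum prey-to-predator biomass ratio sustaining predator
           growth (prey/pred)
    eps    alternative-prey floor (prey/ha); the predator survives at
           density eps/q without the focal prey
    """

    r: float
    c: float
    alpha: float
    beta: float
    s: float
    q: float
    mu: float
    nu: float
    eps: float

    model_id = 1
    model_name = "may"

    def __post_init__(self) -> None:
        _require_positive(r=self.r, c=self.c, alpha=self.alpha,
                          beta=self.beta, s=self.s, q=self.q,
                          mu=self.mu, nu=self.nu, eps=self.eps)

    def with_r(self, r: float) -> "MayParams":
        return replace(self, r=r)

    def to_array(self) -> np.ndarray:
        return np.array([self.c, self.alpha, self.beta, self.mu, self.nu,
                         self.s, self.q, self.eps])


ModelParams = RMAParams | MayParams


def table1(model: str, **overrides: float) -> ModelParams:
    """Bundled lynx-hare parameter values for ``model`` in {'rma', 'may'}.

    Keyword overrides replace individual fields (e.g. ``table1('rma',
    r=2.0)``).
    """
    model = model.lower()
    if model not in ("rma", "may"):
        raise ValueError(f"unknown model {model!r}; expected 'rma' or 'may'")
    ref = resources.files("phasetip.params") / f"{model}_table1.json"
    raw = json.loads(ref.read_text())
    raw.pop("model")
    raw.pop("description")
    raw.update(overrides)
    cls = RMAParams if model == "rma" else MayParams
    return cls(**raw)


def _prey_rate(N: float, P: float, p: ModelParams) -> float:
    # r*N*(1 - (c/r)N) == N*(r - c*N); written this way the frozen field
    # is polynomial over (nu+N)(beta+N) and exact at N = 0
    return (N * (p.r - p.c * N) * (N - p.mu) / (p.nu + N)
            - p.alpha * N * P / (p.beta + N))


def rma_vector_field(x, p: RMAParams) -> np.ndarray:
    """Time derivative (dN/dt, dP/dt) of the RMA model at state x."""
    N, P = float(x[0]), float(x[1])
    dN = _prey_rate(N, P, p)
    dP = p.chi * p.alpha * N * P / (p.beta + N) - p.delta * P
    return np.array([dN, dP])


def may_vector_field(x, p: MayParams) -> np.ndarray:
    """Time derivative (dN/dt, dP/dt) of the May model at state x."""
    N, P = float(x[0]), float(x[1])
    dN = _prey_rate(N, P, p)
    dP = p.s * P * (1.0 - p.q * P / (N + p.eps))
    return np.array([dN, dP])


def vector_field(x, p: ModelParams) -> np.ndarray:
    if isinstance(p, RMAParams):
        return rma_vector_field(x, p)
    return may_vector_field(x, p)


def jacobian(x, p: ModelParams) -> np.ndarray:
    """Analytic Jacobian of the frozen vector field at state x."""
    N, P = float(x[0]), float(x[1])
    # d/dN of N*(r - cN)*(N - mu)/(nu + N)
    u = N * (p.r - p.c * N) * (N - p.mu)
    du = (p.r - 2.0 * p.c * N) * (N - p.mu) + N * (p.r - p.c * N)
    dA = (du * (p.nu + N) - u) / (p.nu + N) ** 2
    j11 = dA - p.alpha * P * p.beta / (p.beta + N) ** 2
    j12 = -p.alpha * N / (p.beta + N)
    if isinstance(p, RMAParams):
        j21 = p.chi * p.alpha * P * p.beta / (p.beta + N) ** 2
        j22 = p.chi * p.alpha * N / (p.beta + N) - p.delta
    else:
        j21 = p.s * p.q * P ** 2 / (N + p.eps) ** 2
        j22 = p.s * (1.0 - 2.0 * p.q * P / (N + p.eps))
    return np.array([[j11, j12], [j21, j22]])


@dataclass(frozen=True)
class Equilibrium:
    """A stationary state with its linearization.

    label       e0 (extinction), e1 (prey-only), e2 (Allee),
                e3 / e4 (coexistence)
    stability   'attractor', 'saddle' or 'repeller' from the eigenvalue
                real parts (tolerance 1e-8)
    """

    location: np.ndarray
    label: str
    eigenvalues: np.ndarray
    stability: str


_STAB_TOL = 1e-8


def _make_eq(x, label: str, p: ModelParams) -> Equilibrium:
    x = np.asarray(x, dtype=float)
    lam = np.linalg.eigvals(jacobian(x, p))
    re = np.sort(lam.real)
    if re[1] < -_STAB_TOL:
        stab = "attractor"
    elif re[0] > _STAB_TOL:
        stab = "repeller"
    elif re[0] < -_STAB_TOL < _STAB_TOL < re[1]:
        stab = "saddle"
    else:
        stab = "nonhyperbolic"
    return Equilibrium(location=x, label=label, eigenvalues=lam,
                       stability=stab)


def extinction_state(p: ModelParams) -> np.ndarray:
    """The extinction attractor: (0, 0) for RMA, (0, eps/q) for May.

    In the May model the predator falls back on alternative prey, so
    'extinction' means loss of the focal prey with the predator parked
    at the low density eps/q.
    """
    if isinstance(p, RMAParams):
        return np.zeros(2)
    return np.array([0.0, p.eps / p.q])


def coexistence_equilibrium(p: ModelParams) -> np.ndarray:
    """Location of e3(r), the coexistence equilibrium the cycle encircles."""
    if isinstance(p, RMAParams):
        N3 = p.delta * p.beta / (p.chi * p.alpha - p.delta)
        P3 = (p.r / p.alpha * (1.0 - p.c * N3 / p.r) * (p.beta + N3)
              * (N3 - p.mu) / (p.nu + N3))
        return np.array([N3, P3])
    roots = _may_coexistence_roots(p)
    if not roots:
        raise ValueError(f"no coexistence equilibrium for May at r={p.r}")
    N3 = roots[-1]
    return np.array([N3, (N3 + p.eps) / p.q])


def _may_coexistence_roots(p: MayParams) -> list[float]:
    """Prey densities of the May coexistence equilibria.

    Substitutes the non-trivial predator nullcline P = (N + eps)/q into
    the prey equation and brackets sign changes of the resulting scalar
    function on (0, r/c].  Typically two roots: e4 (saddle, near the
    Allee density mu) and e3 (inside the cycle).
    """

    def g(N: float) -> float:
        return ((p.r - p.c * N) * (N - p.mu) / (p.nu + N)
                - p.alpha * (N + p.eps) / (p.q * (p.beta + N)))

    n_hi = p.r / p.c
    grid = np.linspace(1e-6, n_hi, 4000)
    vals = np.array([g(N) for N in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-12))
    return roots


def equilibria(p: ModelParams) -> list[Equilibrium]:
    """All non-negative equilibria of the frozen model, with stability.

    RMA uses the closed forms e0 = (0,0), e1 = (r/c, 0), e2 = (mu, 0),
    e3 = (N3, P3(r)); absent coexistence states (P3 < 0) are omitted.
    May solves the nullcline system numerically for e3/e4 and anchors
    e0 at (0, eps/q).
    """
    eqs = [_make_eq(extinction_state(p), "e0", p),
           _make_eq([p.r / p.c, 0.0], "e1", p),
           _make_eq([p.mu, 0.0], "e2", p)]
    if isinstance(p, RMAParams):
        x3 = coexistence_equilibrium(p)
        if x3[1] >= 0 and x3[0] <= p.r / p.c:
            eqs.append(_make_eq(x3, "e3", p))
    else:
        roots = _may_coexistence_roots(p)
        labels = ["e4", "e3"] if len(roots) == 2 else ["e3"]
        # by convention e3 is the larger-N coexistence state (inside the
        # cycle) and e4 the saddle near the Allee density
        for N, lab in zip(sorted(roots), labels):
            eqs.append(_make_eq([N, (N + p.eps) / p.q], lab, p))
    return eqs


def saddle_equilibrium(p: ModelParams) -> Equilibrium:
    """The saddle whose stable manifold is the Allee threshold.

    e2 for the RMA model; the coexistence saddle e4 for the May model.
    """
    label = "e2" if isinstance(p, RMAParams) else "e4"
    for eq in equilibria(p):
        if eq.label == label:
            if eq.stability != "saddle":
                raise ValueError(
                    f"{label} at r={p.r} is not a saddle "
                    f"(eigenvalues {eq.eigenvalues})")
            return eq
    raise ValueError(f"saddle {label} not found at r={p.r}")
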