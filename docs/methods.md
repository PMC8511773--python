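# Methods

`phasetip` studies how year-to-decade climate variability tips cyclic
predator–prey systems into extinction, and in particular the *phase
tipping* mechanism: a drop in prey resources is lethal only when it
arrives during certain phases of the predator–prey cycle. This note
records the models, the numerical procedures, the parameter choices and
their rationale, and the known limitations.

## Models

Two planar vector fields with a strong Allee effect in the prey, both
parameterized for the Canada lynx / snowshoe hare system (densities in
animals per hectare, rates per year). Writing N for prey and P for
predator density,

```
dN/dt = r N (1 − (c/r) N) (N − μ)/(ν + N) − α N P/(β + N)
```

is shared by both models. The Rosenzweig–MacArthur (RMA) predator dies
out exponentially without the focal prey,

```
dP/dt = χ α N P/(β + N) − δ P,
```

while the May (Leslie–Gower) predator has alternative prey and persists
at density ε/q when N = 0:

```
dP/dt = s P (1 − q P/(N + ε)).
```

The prey growth rate r doubles as the climate proxy: the carrying
capacity is r/c. Bundled defaults (`phasetip.models.table1`): RMA
c = 0.19, α = 800, β = 1.5, χ = 0.004, δ = 2.2, μ = 0.03, ν = 0.003;
May c = 0.22, α = 505, β = 0.3, s = 0.85, q = 205, ε = 0.031, with the
same Allee parameters. All computations use these units verbatim; no
internal rescaling.

Equilibria: the RMA coexistence state has the closed form
N₃ = δβ/(χα − δ), P₃(r) = (r/α)(1 − cN₃/r)(β + N₃)(N₃ − μ)/(ν + N₃);
degenerate parameter sets with χα ≤ δ are rejected. The May coexistence
states e₃ (inside the cycle) and e₄ (saddle near the Allee density) are
found by substituting the predator nullcline P = (N + ε)/q into the
prey equation and bracketing roots on (0, r/c]. The extinction attractor
is (0, 0) for RMA and (0, ε/q) for May — in the May model "extinction"
means loss of the focal prey with the predator surviving on alternative
prey. The point (0, 0) is also a May equilibrium but is a saddle (the
predator grows at rate s there), so it is not part of the attractor
inventory.

## Phase

Phase is the polar angle about the coexistence equilibrium e₃(r), with
the predator axis stretched by 10³ so prey and predator excursions
contribute comparably: φ = atan2(10³(P − P₃), N − N₃) ∈ [0, 2π). The
cycle rotates counter-clockwise, so φ increases strictly along it; the
same formula assigns a phase to oscillatory states near the cycle. The
10³ factor is fixed, not adaptive. The same weighting defines the
*scaled metric* `hypot(ΔN, 10³ ΔP)` used for every distance in the
package (Poincaré return tolerances, threshold distances, proximity
tests).

## Limit cycles

Cycles are located by integrating from a small radial perturbation
(10⁻⁵ in N) of e₃(r) and detecting upward crossings of the Poincaré ray
{P = P₃, N > N₃}. Each crossing is refined by bisection on a single
embedded Runge–Kutta step — linear interpolation across an adaptive
step is orders of magnitude too coarse for the 10⁻⁹ return tolerance.
Successive returns within 10⁻⁹ (scaled) declare convergence; the period
is the time between the last two returns and one period is then sampled
at equal time steps. The hunt uses rtol 10⁻¹⁰ / atol 10⁻¹³ so that the
numerical return map is reproducible below the return tolerance; the
integrator is a hand-rolled Dormand–Prince 5(4) compiled with numba,
because the basin machinery performs 10⁴–10⁶ short integrations and
`solve_ivp` call overhead would dominate.

Cycle *existence* (used by the interval bisections) additionally
classifies slow non-converged hunts by the trend of the section radius
— growth from the 10⁻⁵ seed means an attracting cycle is forming,
decay means e₃ attracts — and falls back on the sign of Re λ(e₃) in the
rare truly ambiguous case, which is exact at the oscillatory onset.
With this, the bisection endpoints agree with the independent
eigenvalue-based Hopf location to better than 10⁻³.

The cycle-existence intervals are resolved to 10⁻³ by bisection inside
a user-supplied bracket. For the RMA model the upper endpoint is the
heteroclinic value r_h where predator depletion joins the cycle (the
cycle's minimum P → 0 and the period grows); past r_h only extinction
remains.

The invariant measure of a cycle is the fraction of the period spent in
each of 64 phase bins (the bin count is a parameter; 64 resolves the
strongly non-uniform measure without noise). With equal-time samples
this is a plain histogram of sample phases; it was cross-checked
against direct timestep counting on an independent dense trajectory.

## Basin membership

The frozen system in the bistable regime has exactly two attractors:
the cycle and the extinction state. Membership is decided by forward
integration with three verdicts:

* **extinction** once N < μ — below the Allee density both prey terms
  are negative in both models, so prey decline is monotone and
  extinction certain; this is a rigorous early exit — or once the state
  enters the 10⁻⁴ ball of the extinction attractor;
* **cycle** once the state has stayed within 0.05 (scaled) of the
  sampled cycle for a *continuous 1.25 cycle periods*. Transient
  proximity is deliberately not enough: doomed trajectories brush past
  the cycle in the low-prey corridor where the basin boundary runs
  within ~0.04 of the cycle, and an instantaneous proximity test
  misclassifies them (this failure mode was diagnosed against scipy's
  Radau integrator and is the reason for the sustained-proximity rule);
* **boundary-undecided** when the time cap (500 yr default) expires,
  reported explicitly and never silently classified.

## Allee threshold θ(r)

θ(r) is the stable manifold of the saddle es(r) — the Allee saddle
e₂ = (μ, 0) for RMA, the coexistence saddle e₄(r) for May — grown by
backward-time integration from ±10⁻⁶ offsets along the stable
eigenvector, truncated at a box (default 3× the cycle's bounding box;
callers comparing against cycles from other r values pass a box
covering those too) and decimated to ~10⁻³-spaced polyline points.
For global side-of-threshold tests the open curve is closed along the
box perimeter into a polygon; of the two possible closures the one
*not* containing e₃(r) is the extinction region (shapely does the
point-in-polygon work). Points within a tangency band (0.02 scaled by
default) of the curve are reported as boundary.

## Basin instability

To test whether the cycle Γ(r₁) lies inside the basin of Γ(r₂), the
cycle is resampled at 4000 points equally spaced in **scaled arc
length** and each point is forward-integrated under the frozen system
at r₂. Equal-time sampling — natural for the invariant measure — fails
here: the narrow tangency arcs live in the fast prey-crash segment
where equal-time samples are sparse, and with time sampling the May
onset appears ~0.4 too low. Classes: `none` (no point outside),
`partial`, `total`, with `marginal`/`almost_total` flagged when the
out-/in-fraction falls below a tangency tolerance (0.2% of the arc) —
exact closure membership is not computable in floating point. The
classifier refuses to decide if >1% of points are unresolved.

The onset of partial basin instability along a decreasing-r path is
bisected to 10⁻³ on the none/partial transition. The membership scan
visits arc points in golden-ratio order so that any unstable arc is hit
early, which makes the "partial" side of each bisection step cheap.

Two independent membership routes — forward integration and the
geometric θ side test — agree at 500/500 test phases for both reference
configurations (RMA 2.47→1.8, May 3.3→2.0), and this equivalence (the
single-switch criterion for phase tipping) is enforced in the test
suite with zero tolerated disagreements outside the tangency band.

## Climate forcing

r(t) is piecewise constant: amplitudes i.i.d. uniform on [r₂, r₁],
dwell times geometric. The printed form of the dwell distribution,
g(ℓ) = (1−ρ)^ℓ ρ over ℓ ≥ 1, does not sum to one; following the
Bernoulli-trials description the implementation uses
ℓ = 1 + (failures before first success), support {1, 2, …}, mean 1/ρ
(`numpy.random.Generator.geometric`). Switches land on whole-year
boundaries; the time unit is years. ρ = 0.2 (mean dwell 5 yr) is the
default, a realistic value for boreal-forest climate records. Years are
classed high-productivity when the amplitude strictly exceeds the
interval midpoint. Identical (seed, spec) pairs reproduce bit-identical
paths.

## Tipping experiments

The non-autonomous system is integrated segment by segment with the
state continuous across switches. A run has converged to extinction
when the state enters the 10⁻⁴ ball of the extinction attractor and is
still inside it at the end of that segment. The collapse is attributed
to the *causal switch*: walking backward from the collapse segment, the
first switch whose state no longer returns to the cycle's basin under
its own frozen amplitude; the tipping time t₁, state x_b, phase φ(x_b)
(w.r.t. e₃ at the pre-switch amplitude) and the amplitude pair
(r_pre, r_post) are recorded. Classification: bifurcation-driven (B)
tipping iff r_post exceeds the heteroclinic level r_h; phase (P)
tipping otherwise — always, in the May model, which has no dangerous
cycle bifurcation. A run in which r(t) crosses r_h but switches back
before the collapse completes is not a tipping event.

Monte-Carlo ensembles draw one independent forcing realization per run
from per-run RNG streams spawned off a master seed (reproducible,
order-independent). Runs surviving the 5000-yr horizon are counted
separately and replaced, never silently dropped. Rescue events —
excursions out of the cycle's basin undone by a later switch — are
detected on demand by evaluating membership at every switch.

Ensemble sizes: the test suite uses 100-event ensembles; the
reproduction script uses 1000 events per model (about a minute of
computation for the slower RMA ensemble).

## Numerical choices, in brief

| quantity | value | why |
|---|---|---|
| integrator | Dormand–Prince 5(4), numba | 10⁴–10⁶ short integrations |
| membership rtol/atol | 10⁻⁸ / 10⁻¹⁰ | fate decisions, cross-checked vs Radau |
| cycle-hunt rtol/atol | 10⁻¹⁰ / 10⁻¹³ | return map below return tolerance |
| Poincaré return tol | 10⁻⁹ scaled | generous for multi-annual cycles |
| time caps | 5000 yr (hunt), 500 yr (membership) | periods are ~8–12 yr |
| manifold offset | 10⁻⁶ along stable eigenvector | standard manifold seeding |
| extinction ball | 10⁻⁴ around the extinction attractor | e₀ is asymptotically stable |
| negative-density guard | clip in (−10⁻⁹, 0) to 0 | flow preserves positivity |
| arc samples | 4000 | resolves arcs ≳ 0.03% of the cycle |
| bisection resolutions | 10⁻³ in r (10⁻⁴ Hopf) | below every reported precision |

## Limitations

* The membership early exits assume the bistable inventory
  {cycle, extinction}; in monostable regimes the cycle-proximity
  verdict is simply never triggered.
* θ(r) is a truncated polyline; points outside the truncation box are
  classified by the polygon closure, which is only as good as the box.
  The backward-grown manifold was validated against forward integration
  inside the boxes used here.
* The basin-instability monotonicity along decreasing-r paths is checked
  empirically on the tested brackets, not asserted globally.
* Smoothly ramped inputs (rate-dependent tipping), isochrone or
  Hilbert-transform phases, tori/chaotic base states and early-warning
  indicators are out of scope.
* The May upper cycle-loss endpoint (≈3.81) is reported by the existence
  scan without asserting the bifurcation type by which the cycle
  disappears there.
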