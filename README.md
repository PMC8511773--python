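# phasetip

Phase tipping in cyclic predator–prey systems under piecewise-constant
climate forcing.

Cyclic ecosystems can collapse when external conditions shift — but for
a system living on a limit cycle, *when* in the cycle the shift arrives
matters as much as how large it is. `phasetip` implements the analysis
of this **phase tipping (P-tipping)** mechanism for two paradigmatic
predator–prey models with a strong Allee effect, parameterized for the
Canada lynx / snowshoe hare system: the Rosenzweig–MacArthur (RMA)
model and the May (Leslie–Gower) model. Climate variability enters as a
piecewise-constant prey growth rate r(t) (equivalently, a fluctuating
carrying capacity r/c) with uniform amplitudes and geometric dwell
times. The package is for theoretical ecologists and dynamical-systems
researchers who want to simulate these collapses, and — more
importantly — predict them geometrically.

## What it computes

* **Frozen models** (`phasetip.models`): both vector fields, analytic
  Jacobians, all equilibria with stability, bundled lynx–hare parameter
  values.
* **Limit cycles and phase** (`phasetip.cycles`): the attracting cycle
  Γ(r) by Poincaré-return integration, the phase
  φ = atan2(10³(P−P₃), N−N₃) anchored at the coexistence equilibrium,
  the cycle-existence interval in r, and the cycle's invariant measure
  μ(φ) (the expected phase distribution of bifurcation-driven tipping).
* **Basin geometry** (`phasetip.basins`): the Allee threshold θ(r) —
  the basin boundary, computed as the stable manifold of a saddle —
  basin membership, and the **partial basin instability**
  classification: which phases of Γ(r₁) land outside the basin of
  Γ(r₂) when r drops from r₁ to r₂. A single switch r₁ → r₂ tips the
  system if and only if it is applied at one of those phases.
* **Climate forcing** (`phasetip.climate`): reproducible piecewise-
  constant r(t) realizations (uniform amplitudes on [r₂, r₁], geometric
  dwells with mean 1/ρ, default ρ = 0.2).
* **Tipping engine** (`phasetip.tipping`): non-autonomous switching
  simulations, detection and attribution of tipping events (tipping
  time, state, phase, pre/post amplitudes), B-vs-P classification
  against the dangerous heteroclinic level r_h, rescue events, and
  Monte-Carlo ensembles.
* **Bifurcation scans** (`phasetip.scan`): Hopf onset, heteroclinic
  r_h, and the four-regime classification of the (r, δ) / (r, q)
  planes by attractor inventory.

## Worked example

Which phases of the RMA cycle at r₁ = 2.47 are lethal if the prey
growth rate drops to r₂ = 1.8?

```python
import numpy as np
from phasetip import models, basins, tipping

rma = models.table1("rma")                      # lynx-hare parameters
res = basins.classify_basin_instability(rma.with_r(2.47), rma.with_r(1.8))
print(res.klass, round(res.out_fraction, 3))
for lo, hi in res.arcs:
    print(f"basin-unstable phases: {lo:.2f} .. {hi:.2f} rad")

# the same question answered by brute force: switch exactly at phase pi/2
print(tipping.single_switch_tips(rma, 2.47, 1.8, np.pi / 2))
print(tipping.single_switch_tips(rma, 2.47, 1.8, 3 * np.pi / 2))
```

prints

```
partial 0.103
basin-unstable phases: 1.37 .. 1.80 rad
True
False
```

So 10.3% of the cycle (by arc length) is basin-unstable, in a single
phase arc around φ = π/2 — the part of the cycle where prey decline is
fastest and predator pressure highest. A switch applied there tips the
ecosystem to extinction; the same switch applied half a cycle later
(φ = 3π/2, fast prey growth, few predators) is harmless. Under random
multi-switch forcing on [1.6, 2.5] every collapse is a phase-tipping
event, and the collapse states cluster in exactly these phases:

```python
from phasetip.climate import ClimateSpec
spec = ClimateSpec(r_low=1.6, r_high=2.5, rho=0.2, horizon=5000.0)
mc = tipping.monte_carlo(rma, spec, (3.0, 0.002), n_events=50, seed=42,
                         rh=2.6086)
print(mc.counts(), round(mc.to_frame().phase.median(), 2))
```

```
{'B': 0, 'P': 50} 1.58
```

(median tipping phase 1.58 ≈ π/2).

A `phasetip` console command exposes the main workflows
(`simulate`, `montecarlo`, `bi-region`, `bifurcate`, `switch-map`);
every run logs its seed and config digest and writes CSV/JSON.

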