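"""Machine-readable summaries of tipping ensembles.

Produces the tabular twins of the usual diagnostic panels: the
(r_pre, r_post) switch scatter, tipping-phase histograms split by
tipping class (on the same bins as the cycle's invariant measure so
the overlay is directly comparable), and the tipping-time
distribution.  For the bifurcation-driven class the phase histogram is
expected to track the invariant measure closely; for phase tipping it
is concentrated and uncorrelated with it -- the reported correlations
quantify both statements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cycles import InvariantMeasure
from .tipping import MonteCarloResult

__all__ = ["report_ensemble"]


def _phase_hist(phases: np.ndarray, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(np.mod(phases, 2.0 * np.pi), bins=edges)
    return counts


def report_ensemble(result: MonteCarloResult,
                    measure: InvariantMeasure | None = None,
                    n_bins: int = 64) -> dict:
    """Summary bundle for a Monte-Carlo ensemble.

    Returns a dict with keys 'events', 'switch_scatter', 'phase_hist',
    'tipping_times', 'counts' and, when an invariant measure is given,
    'correlation' (Pearson correlation of each class's phase histogram
    with the measure).
    """
    if result.n_events == 0:
        raise ValueError("empty ensemble")
    events = result.to_frame()
    edges = (measure.bin_edges if measure is not None
             else np.linspace(0.0, 2.0 * np.pi, n_bins + 1))
    hists = {}
    for klass in ("B", "P"):
        ph = events.loc[events["class"] == klass, "phase"].to_numpy()
        hists[klass] = _phase_hist(ph, edges)
    phase_hist = pd.DataFrame({
        "bin_lo": edges[:-1],
        "bin_hi": edges[1:],
        "B": hists["B"],
        "P": hists["P"],
    })
    out = {
        "events": events,
        "switch_scatter": events[["r_pre", "r_post", "class"]],
        "phase_hist": phase_hist,
        "tipping_times": events[["t1", "class"]],
        "counts": result.counts(),
    }
    if measure is not None:
        corr = {}
        for klass in ("B", "P"):
            h = hists[klass].astype(float)
            if h.sum() > 0 and h.std() > 0 and measure.masses.std() > 0:
                corr[klass] = float(np.corrcoef(h, measure.masses)[0, 1])
            else:
                corr[klass] = float("nan")
        out["correlation"] = corr
    return out
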