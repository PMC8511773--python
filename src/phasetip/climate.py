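"""Piecewise-constant random climate forcing r(t).

Climate variability on year-to-decade timescales is modelled by two
independent random processes: the amplitude of r(t) is uniform on a
closed interval [r_low, r_high], and the dwell time (the number of
consecutive years the amplitude stays constant) is geometric.  The
dwell convention follows the Bernoulli-trials picture: a switch is
attempted each year with probability ``rho`` of success, so dwell
lengths are ``1 + (failures before the first success)`` with support
{1, 2, ...} and mean 1/rho.  Amplitudes are redrawn independently at
every switch; consecutive equal values are allowed.  A realistic value
for boreal-forest climate records is rho = 0.2 (mean dwell 5 years).

Switches happen at whole-year boundaries: the unit of time is years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClimateSpec",
    "ClimatePath",
    "sample_dwell",
    "sample_amplitude",
    "generate_path",
    "classify_years",
]


@dataclass(frozen=True)
class ClimateSpec:
    """Specification of the climate-forcing process.

    r_low, r_high  amplitude interval [r2, r1] (1/yr)
    rho            yearly switching probability in (0, 1]
    seed           RNG seed (None draws fresh entropy)
    horizon        maximum length of a generated path in years
    """

    r_low: float
    r_high: float
    rho: float = 0.2
    seed: int | None = None
    horizon: float = 5000.0

    def __post_init__(self) -> None:
        if not self.r_low < self.r_high:
            raise ValueError("require r_low < r_high")
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("require rho in (0, 1]")
        if self.horizon < 0:
            raise ValueError("require horizon >= 0")


@dataclass(frozen=True)
class ClimatePath:
    """An ordered realization of (dwell, amplitude) segments.

    dwells      integer years per segment, each >= 1
    amplitudes  r value per segment, each in [r_low, r_high]
    """

    dwells: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        if self.dwells.shape != self.amplitudes.shape:
            raise ValueError("dwells and amplitudes must align")

    @property
    def n_segments(self) -> int:
        return int(self.dwells.shape[0])

    @property
    def switch_times(self) -> np.ndarray:
        """Start year of each segment (first is 0)."""
        return np.concatenate(([0.0], np.cumsum(self.dwells)[:-1]))

    @property
    def total_years(self) -> float:
        return float(self.dwells.sum())

    def r_at(self, t: float) -> float:
        """Amplitude in force at time t (segments are left-closed)."""
        idx = int(np.searchsorted(np.cumsum(self.dwells), t, side="right"))
        idx = min(idx, self.n_segments - 1)
        return float(self.amplitudes[idx])

    def to_frame(self, spec: ClimateSpec | None = None):
        import pandas as pd
        df = pd.DataFrame({
            "segment": np.arange(self.n_segments),
            "start_year": self.switch_times,
            "dwell": self.dwells,
            "amplitude": self.amplitudes,
        })
        if spec is not None:
            df["type"] = classify_years(self, spec)
        return df

    @classmethod
    def from_frame(cls, df) -> "ClimatePath":
        return cls(dwells=df["dwell"].to_numpy(dtype=np.int64),
                   amplitudes=df["amplitude"].to_numpy(dtype=float))


def sample_dwell(rho: float, rng: np.random.Generator) -> int:
    """One geometric dwell length (years >= 1, mean 1/rho)."""
    if not 0.0 < rho <= 1.0:
        raise ValueError("require rho in (0, 1]")
    return int(rng.geometric(rho))


def sample_amplitude(spec: ClimateSpec, rng: np.random.Generator) -> float:
    """One uniform amplitude on [r_low, r_high]."""
    return float(rng.uniform(spec.r_low, spec.r_high))


def generate_path(spec: ClimateSpec,
                  rng: np.random.Generator | None = None) -> ClimatePath:
    """Draw (dwell, amplitude) segments until the horizon is covered.

    The last segment may overshoot the horizon; consumers cap the
    simulation at the horizon.  A zero horizon yields an empty path.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    dwells: list[int] = []
    amps: list[float] = []
    covered = 0.0
    while covered < spec.horizon:
        ell = sample_dwell(spec.rho, rng)
        dwells.append(ell)
        amps.append(sample_amplitude(spec, rng))
        covered += ell
    return ClimatePath(dwells=np.asarray(dwells, dtype=np.int64),
                       amplitudes=np.asarray(amps, dtype=float))


def classify_years(path: ClimatePath, spec: ClimateSpec) -> np.ndarray:
    """Per-segment productivity class: 'H' above the interval mean, else 'L'.

    The comparison is strict: an amplitude exactly at (r_low + r_high)/2
    counts as low-productivity.
    """
    mean = 0.5 * (spec.r_low + spec.r_high)
    return np.where(path.amplitudes > mean, "H", "L")
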