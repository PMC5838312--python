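"""Per-phase specific rates from batch time-course measurements.

The batch cultures show four growth phases with fixed default boundaries
(0-48, 48-104, 104-168, 168-264 h).  Within each phase the specific growth
rate is the slope of an ordinary least-squares fit of ln(biomass) against
time, and each metabolite's specific rate is obtained from a linear
regression used to predict the concentration at the end of the phase:

    q = (predicted final - phase start value) / integral of biomass over the phase

The regression is performed against the fitted biomass-time integral
(equivalently, time re-scaled by biomass), which is the exact linearization
of ``dC/dt = q·X`` during exponential growth; on noiseless data this
recovers the generating rates to machine precision.  Phase start values are
the experiment's initial concentrations for phase I and the previous
phase's predicted final values for later phases.  The stationary phase (IV)
is segmented but excluded from downstream flux modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: default phase cut points, hours
DEFAULT_PHASE_BOUNDARIES: Tuple[float, ...] = (0.0, 48.0, 104.0, 168.0, 264.0)

#: OD600 -> dry cell weight calibration coefficients (gDCW/L per OD, offset)
OD_DCW_SLOPE = 0.8105
OD_DCW_INTERCEPT = 0.0104


class InsufficientDataError(ValueError):
    """Fewer samples than required for a regression."""


def od_to_dcw(od600):
    """Dry cell weight (gDCW/L) from optical density at 600 nm."""
    od = np.asarray(od600, dtype=float)
    if np.any(od < 0):
        raise ValueError("OD600 must be non-negative")
    out = OD_DCW_SLOPE * od + OD_DCW_INTERCEPT
    return float(out) if np.isscalar(od600) else out


def dcw_to_od(dcw):
    """Inverse of the OD600 calibration (used by the data generator)."""
    return (np.asarray(dcw, dtype=float) - OD_DCW_INTERCEPT) / OD_DCW_SLOPE


@dataclass
class TimeCourse:
    """Sampled OD/biomass and concentrations for one culture.

    ``concentrations`` are in mmol/L; ``biomass`` in gDCW/L is derived from
    ``od600`` via the calibration when not given directly.
    """

    times: np.ndarray
    ethanol_level: float = 0.0
    od600: Optional[np.ndarray] = None
    biomass: Optional[np.ndarray] = None
    concentrations: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.od600 is not None:
            self.od600 = np.asarray(self.od600, dtype=float)
            self._check_len(self.od600, "od600")
        if self.biomass is None:
            if self.od600 is None:
                raise ValueError("either od600 or biomass series is required")
            self.biomass = od_to_dcw(self.od600)
        else:
            self.biomass = np.asarray(self.biomass, dtype=float)
            self._check_len(self.biomass, "biomass")
        if np.any(self.biomass <= 0):
            raise ValueError("biomass must be positive after inoculation")
        clean = {}
        for name, series in self.concentrations.items():
            arr = np.asarray(series, dtype=float)
            self._check_len(arr, name)
            if np.any(arr < -1e-9):
                raise ValueError(f"negative concentration in series {name!r}")
            clean[name] = np.clip(arr, 0.0, None)
        self.concentrations = clean

    def _check_len(self, arr: np.ndarray, name: str) -> None:
        if len(arr) != len(self.times):
            raise ValueError(f"series {name!r} length differs from times")

    # -- long-format interchange -----------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.times):
            if self.od600 is not None:
                rows.append((t, "od600", self.od600[i]))
            rows.append((t, "biomass", self.biomass[i]))
            for name, series in self.concentrations.items():
                rows.append((t, name, series[i]))
        df = pd.DataFrame(rows, columns=["time_h", "variable", "value"])
        df["ethanol_pct"] = self.ethanol_level
        df["replicate"] = 1
        return df

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, ethanol_level: Optional[float] = None) -> "TimeCourse":
        """Build from long-format records; replicates are averaged."""
        required = {"time_h", "variable", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"long format requires columns {sorted(required)}")
        if ethanol_level is not None and "ethanol_pct" in df.columns:
            df = df[np.isclose(df["ethanol_pct"].astype(float), ethanol_level)]
        elif ethanol_level is None and "ethanol_pct" in df.columns:
            levels = sorted(df["ethanol_pct"].unique())
            if len(levels) > 1:
                raise ValueError(
                    f"multiple ethanol levels {levels}; pass ethanol_level"
                )
            ethanol_level = float(levels[0])
        wide = (
            df.groupby(["time_h", "variable"])["value"].mean().unstack("variable")
        )
        times = wide.index.to_numpy(dtype=float)
        od = wide["od600"].to_numpy() if "od600" in wide else None
        biomass = wide["biomass"].to_numpy() if "biomass" in wide else None
        conc = {
            c: wide[c].to_numpy()
            for c in wide.columns
            if c not in ("od600", "biomass")
        }
        return cls(
            times=times,
            ethanol_level=ethanol_level or 0.0,
            od600=od,
            biomass=biomass,
            concentrations=conc,
        )


@dataclass(frozen=True)
class PhaseDefinition:
    """Half-open growth-phase interval [t_start, t_end)."""

    phase_id: int
    t_start: float
    t_end: float

    def contains(self, t: np.ndarray, last: bool = False) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if last:  # the final phase keeps its right endpoint
            return (t >= self.t_start) & (t <= self.t_end)
        return (t >= self.t_start) & (t < self.t_end)


def segment_phases(
    timecourse: TimeCourse,
    boundaries: Optional[Sequence[Tuple[float, float]]] = None,
) -> List[PhaseDefinition]:
    """Assign the default (or custom) contiguous phase windows.

    Default windows follow the four-phase layout; windows beyond the last
    sampled time are dropped, and the final kept window is truncated at it.
    """
    t_max = float(timecourse.times[-1])
    t_min = float(timecourse.times[0])
    if boundaries is None:
        cuts = DEFAULT_PHASE_BOUNDARIES
        intervals = list(zip(cuts[:-1], cuts[1:]))
    else:
        intervals = [(float(a), float(b)) for a, b in boundaries]
        for (a, b) in intervals:
            if b <= a:
                raise ValueError(f"empty phase interval ({a}, {b})")
        for (_, b1), (a2, _) in zip(intervals[:-1], intervals[1:]):
            if not np.isclose(b1, a2):
                raise ValueError(
                    f"phase boundaries not contiguous at {b1} vs {a2}"
                )
        if intervals[0][0] < t_min - 1e-9 or intervals[-1][1] > t_max + 1e-9:
            raise ValueError("phase boundaries extend beyond the sampled range")
    phases = []
    for k, (a, b) in enumerate(intervals, start=1):
        if a >= t_max:
            break
        phases.append(PhaseDefinition(k, a, min(b, t_max)))
    return phases


@dataclass
class RateSet:
    """Specific rates for one phase.

    ``q`` follows the signed convention: negative = consumption, positive =
    production (mmol·gDCW⁻¹·h⁻¹).
    """

    phase_id: int
    mu: float
    q: Dict[str, float]
    endpoint_predictions: Dict[str, float]
    start_values: Dict[str, float]
    fit_diagnostics: Dict[str, Tuple[float, float]]  # name -> (r2, resid SD)
    biomass_integral: float
    t_start: float
    t_end: float
    biomass_start: float = 0.0
    biomass_end: float = 0.0


def _ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float, float]:
    """Slope, intercept, r², residual SD of y ~ x."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    sd = float(np.sqrt(ss_res / max(len(y) - 2, 1)))
    return slope, intercept, r2, sd


def estimate_phase_rates(
    timecourse: TimeCourse,
    phase: PhaseDefinition,
    start_values: Optional[Dict[str, float]] = None,
    last_phase: bool = False,
) -> RateSet:
    """Specific growth and metabolite rates for one phase.

    ``start_values`` chains phases: pass the previous phase's
    ``endpoint_predictions`` (phase I uses its own fitted start).
    """
    mask = phase.contains(timecourse.times, last=last_phase)
    t = timecourse.times[mask]
    if len(t) < 3:
        raise InsufficientDataError(
            f"phase {phase.phase_id}: {len(t)} samples, need >= 3"
        )
    X = timecourse.biomass[mask]
    if np.any(X <= 0):
        raise ValueError("non-positive biomass inside phase")
    mu, ln_x0, r2_mu, sd_mu = _ols(t - phase.t_start, np.log(X))
    x0 = float(np.exp(ln_x0))

    # biomass-time integral of the fitted exponential (closed form; for a
    # near-zero growth slope it degenerates to x0·Δt)
    def integral_at(tq):
        tau = np.asarray(tq, dtype=float) - phase.t_start
        if abs(mu) < 1e-12:
            return x0 * tau
        return x0 * (np.exp(mu * tau) - 1.0) / mu

    I_samples = integral_at(t)
    I_end = float(integral_at(phase.t_end))
    total_integral = I_end
    q: Dict[str, float] = {}
    endpoints: Dict[str, float] = {}
    starts: Dict[str, float] = {}
    diagnostics: Dict[str, Tuple[float, float]] = {"__mu__": (r2_mu, sd_mu)}
    for name, series in timecourse.concentrations.items():
        c = series[mask]
        slope, intercept, r2, sd = _ols(I_samples, c)
        pred_end = intercept + slope * I_end
        start = (
            start_values[name]
            if start_values is not None and name in start_values
            else intercept
        )
        q[name] = (pred_end - start) / I_end
        endpoints[name] = pred_end
        starts[name] = start
        diagnostics[name] = (r2, sd)
    return RateSet(
        phase_id=phase.phase_id,
        mu=mu,
        q=q,
        endpoint_predictions=endpoints,
        start_values=starts,
        fit_diagnostics=diagnostics,
        biomass_integral=total_integral,
        t_start=phase.t_start,
        t_end=phase.t_end,
        biomass_start=x0,
        biomass_end=float(x0 * np.exp(mu * (phase.t_end - phase.t_start))),
    )


def estimate_rates(
    timecourse: TimeCourse,
    phases: Optional[List[PhaseDefinition]] = None,
) -> List[RateSet]:
    """Chained per-phase rate estimation over all segmented phases."""
    if phases is None:
        phases = segment_phases(timecourse)
    results: List[RateSet] = []
    prev: Optional[RateSet] = None
    for i, phase in enumerate(phases):
        start_values = prev.endpoint_predictions if prev is not None else None
        rs = estimate_phase_rates(
            timecourse,
            phase,
            start_values=start_values,
            last_phase=(i == len(phases) - 1),
        )
        results.append(rs)
        prev = rs
    return results


def rates_to_frame(rate_sets: Sequence[RateSet]) -> pd.DataFrame:
    """Tidy table of (phase, variable, rate) including mu."""
    rows = []
    for rs in rate_sets:
        rows.append((rs.phase_id, "mu", rs.mu))
        for name, value in sorted(rs.q.items()):
            rows.append((rs.phase_id, name, value))
    return pd.DataFrame(rows, columns=["phase", "variable", "rate"])
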