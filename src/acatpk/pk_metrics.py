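"""Noncompartmental metrics from a plasma concentration-time profile.

Cmax/Tmax come from the dense grid with a local quadratic refinement at the
peak; AUCs use the linear trapezoid with endpoint interpolation, and the
extrapolation to infinity adds C_last / lambda_z with the terminal slope
fitted log-linearly over the final stretch of the profile.  Bioavailability
is the percent of the dose absorbed into the systemic circulation — for a
renally cleared, unmetabolized compound there is no first-pass loss, so
fraction absorbed and systemic availability coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .compound import PKParameters
from .simulator import SimulationResult


class MetricsError(ValueError):
    """Profile unsuitable for the requested metric."""


@dataclass(frozen=True)
class PKMetrics:
    cmax: float  # ng/mL
    tmax: float  # h
    auc_0_24: float  # ng*h/mL
    auc_0_inf: float  # ng*h/mL
    bioavailability: float  # % of dose absorbed

    def __post_init__(self) -> None:
        if self.cmax < 0.0 or self.tmax < 0.0:
            raise MetricsError("cmax and tmax must be non-negative")
        if self.auc_0_24 > self.auc_0_inf * (1.0 + 1e-12) + 1e-12:
            raise MetricsError("AUC0-24 cannot exceed AUC0-inf")
        if not 0.0 <= self.bioavailability <= 100.0 + 1e-9:
            raise MetricsError(f"bioavailability {self.bioavailability} outside [0, 100]%")

    def as_dict(self) -> dict[str, float]:
        return {
            "cmax_ng_per_mL": self.cmax,
            "tmax_h": self.tmax,
            "auc_0_24_ng_h_per_mL": self.auc_0_24,
            "auc_0_inf_ng_h_per_mL": self.auc_0_inf,
            "bioavailability_pct": self.bioavailability,
        }


def auc_trapezoid(time: np.ndarray, conc: np.ndarray, upper: float) -> float:
    """Linear-trapezoid AUC over [time[0], upper], interpolating the endpoint."""
    time = np.asarray(time, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if time.ndim != 1 or time.shape != conc.shape or len(time) < 2:
        raise MetricsError("time and concentration must be matching 1-D grids")
    if np.any(np.diff(time) <= 0.0):
        raise MetricsError("time grid must be strictly increasing")
    if upper > time[-1] + 1e-12 or upper < time[0]:
        raise MetricsError(f"upper limit {upper} h outside grid [{time[0]}, {time[-1]}] h")
    mask = time <= upper
    t = time[mask]
    c = conc[mask]
    if t[-1] < upper:
        t = np.append(t, upper)
        c = np.append(c, np.interp(upper, time, conc))
    return float(np.trapezoid(c, t))


def _refine_peak(time: np.ndarray, conc: np.ndarray) -> tuple[float, float]:
    """Quadratic refinement of the grid maximum; earliest grid point on ties."""
    i = int(np.argmax(conc))  # argmax returns the first (earliest) maximum
    if i == 0 or i == len(conc) - 1:
        return float(conc[i]), float(time[i])
    t0, t1, t2 = time[i - 1 : i + 2]
    c0, c1, c2 = conc[i - 1 : i + 2]
    denom = (c0 - 2.0 * c1 + c2)
    if denom >= 0.0:  # flat or non-concave neighborhood: keep the grid point
        return float(c1), float(t1)
    h = t1 - t0
    delta = 0.5 * (c0 - c2) / denom  # vertex offset in grid units, |delta| <= ~0.5
    tmax = t1 + delta * h
    cmax = c1 - 0.25 * (c0 - c2) * delta
    return float(cmax), float(tmax)


def terminal_slope(time: np.ndarray, conc: np.ndarray, tail_fraction: float = 0.2) -> float:
    """Terminal elimination rate lambda_z (1/h) from a log-linear fit.

    Fits ln(C) against t over the last ``tail_fraction`` of the time span
    (positive concentrations only).  Returns 0 if fewer than three points
    remain or the fitted slope is non-negative (no disposition phase), in
    which case no extrapolation is possible.
    """
    time = np.asarray(time, dtype=float)
    conc = np.asarray(conc, dtype=float)
    t_cut = time[-1] - tail_fraction * (time[-1] - time[0])
    mask = (time >= t_cut) & (conc > 0.0)
    if mask.sum() < 3:
        return 0.0
    fit = stats.linregress(time[mask], np.log(conc[mask]))
    return float(-fit.slope) if fit.slope < 0.0 else 0.0


def compute_metrics(result: SimulationResult, dose: float, pk: PKParameters) -> PKMetrics:
    """Noncompartmental metrics from a completed simulation.

    Requires the profile to cover at least 24 h.  AUC0-inf adds the
    log-linear tail C_end / lambda_z beyond the simulated horizon;
    bioavailability is 100 x total cumulative absorbed / dose.
    """
    time, conc = result.time, result.plasma_conc
    if time[-1] < 24.0:
        raise MetricsError(f"profile covers only {time[-1]} h; 24 h required")

    cmax, tmax = _refine_peak(time, conc)
    auc24 = auc_trapezoid(time, conc, 24.0)
    auc_end = auc_trapezoid(time, conc, float(time[-1]))
    lam = terminal_slope(time, conc)
    tail = conc[-1] / lam if lam > 0.0 and conc[-1] > 0.0 else 0.0
    f_pct = 100.0 * result.cumulative_absorbed[-1].sum() / dose
    return PKMetrics(
        cmax=cmax,
        tmax=tmax,
        auc_0_24=auc24,
        auc_0_inf=auc_end + tail,
        bioavailability=f_pct,
    )
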