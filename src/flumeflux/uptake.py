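"""First-order solute uptake from recirculating decay curves.

Glucose and bulk dissolved organic carbon are injected into a recirculating
flume and their concentration decline monitored over several hours.  Under
first-order removal c(t) = c0*exp(-k t); the loss rate k comes from an
ordinary least-squares fit of ln(c) on t, and the mass transfer coefficient
(uptake velocity) is v_f = k * h_bar, where h_bar is the recirculating
water volume over the wetted streambed area, in cm (approximated by mean
water depth).  v_f has units of length/time and is independent of depth and
velocity scaling, so it is comparable across flumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DecaySeries", "UptakeResult", "fit_decay", "vf_from_k", "control_correct"]


@dataclass
class DecaySeries:
    """(time, concentration) pairs from one recirculating injection."""

    times_h: np.ndarray
    concentrations: np.ndarray
    solute: str = "DOC"
    flume: int | None = None
    biofilm_age_d: float | None = None

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times_h.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must align")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_h": self.times_h, "conc": self.concentrations}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "DecaySeries":
        df = pd.read_csv(path)
        return cls(df["time_h"].to_numpy(), df["conc"].to_numpy(), **meta)


@dataclass(frozen=True)
class UptakeResult:
    k_per_h: float
    vf_cm_h: float
    r_squared: float
    n: int
    no_net_uptake: bool  # flagged when k <= 0
    vf_net_cm_h: float | None = None


def fit_decay(series: DecaySeries) -> tuple[float, float]:
    """Loss rate k (1/h) and r² from a log-linear fit of concentration vs time.

    k is minus the least-squares slope of ln(c) on t.  k <= 0 (no net
    uptake) is legal and left to the caller to flag; nonpositive
    concentrations are rejected before the log transform.
    """
    if series.times_h.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(series.concentrations <= 0):
        raise ValueError("nonpositive concentration; cannot log-transform")
    res = stats.linregress(series.times_h, np.log(series.concentrations))
    r2 = float(res.rvalue**2)
    if np.isnan(res.rvalue):  # constant series: slope 0, correlation undefined
        r2 = 1.0 if np.allclose(series.concentrations, series.concentrations[0]) else 0.0
    return float(-res.slope), r2


def vf_from_k(k_per_h: float, h_bar_cm: float) -> float:
    """Mass transfer coefficient v_f = k * h_bar in cm/h (h_bar = V/A in cm)."""
    if h_bar_cm <= 0:
        raise ValueError("depth equivalent h_bar must be positive")
    return k_per_h * h_bar_cm


def control_correct(vf_biofilm: float, vf_control: float) -> float:
    """Net biological uptake velocity: biofilm minus biofilm-free control."""
    return vf_biofilm - vf_control


def uptake_from_series(series: DecaySeries, h_bar_cm: float,
                       vf_control: float | None = None) -> UptakeResult:
    """Convenience wrapper: fit the decay and convert to v_f in one step."""
    k, r2 = fit_decay(series)
    vf = vf_from_k(k, h_bar_cm)
    net = control_correct(vf, vf_control) if vf_control is not None else None
    return UptakeResult(k_per_h=k, vf_cm_h=vf, r_squared=r2, n=series.times_h.size,
                        no_net_uptake=k <= 0, vf_net_cm_h=net)
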