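"""Growth rates, specific exchange rates, yields, and derived arithmetic.

Implements the standard fermentation bookkeeping for batch cultures:

* growth rate as the slope of ln(biomass) against time in the exponential
  window;
* specific rates r_M = mu * (c_M,e - c_M,s)/(c_X,e - c_X,s) for growing
  cultures (quasi-steady state in the exponential phase) and
  r_M = (c_M,e - c_M,s)/X_av/dt for growth-arrested cultures;
* product yields as regression slopes of delta(product) against
  delta(glucose);
* percent changes and cumulated carbon yields
  (sum_i Y_i * C_i / 6 mol product carbon per mol glucose carbon).

Concentrations are mmol/l (biomass gDW/l), times hours, rates mmol/gDW/h.
An OD420 column is converted to biomass with 0.22 gDW/l per OD unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TimeCourse",
    "RateSummary",
    "OD420_TO_GDW_PER_L",
    "CARBON_ATOMS",
    "fit_growth_rate",
    "specific_rate_growth",
    "specific_rate_arrest",
    "yield_regression",
    "percent_change",
    "carbon_yield",
    "rates_from_timecourse",
]

#: one OD420 unit corresponds to this much biomass (gDW/l)
OD420_TO_GDW_PER_L = 0.22

#: carbon atoms per molecule of each fermentation product
CARBON_ATOMS = {"eth": 2, "ace": 2, "for": 1, "lac": 3, "suc": 4}

ANALYTES = ["glc", "eth", "ace", "for", "lac", "suc"]


@dataclass
class TimeCourse:
    """Sampled batch-culture time series.

    ``data`` columns: ``time_h``, ``biomass_gDW_l`` (or ``od420``), and
    one column per analyte (mmol/l).
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if "od420" in df.columns and "biomass_gDW_l" not in df.columns:
            df = df.assign(biomass_gDW_l=df["od420"] * OD420_TO_GDW_PER_L)
            self.data = df
        t = df["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if (df["biomass_gDW_l"] <= 0).any():
            raise ValueError("biomass must be > 0")
        for col in self.analytes:
            if (df[col] < 0).any():
                raise ValueError(f"negative concentration in {col!r}")

    @property
    def times(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(dtype=float)

    @property
    def biomass(self) -> np.ndarray:
        return self.data["biomass_gDW_l"].to_numpy(dtype=float)

    @property
    def analytes(self) -> list[str]:
        return [c for c in self.data.columns
                if c not in ("time_h", "biomass_gDW_l", "od420")]

    def concentration(self, analyte: str) -> np.ndarray:
        return self.data[analyte].to_numpy(dtype=float)


@dataclass
class RateSummary:
    mu: float
    rates: dict[str, float]
    yields: dict[str, float] = field(default_factory=dict)
    mu_sd: float = 0.0
    rate_sds: dict[str, float] = field(default_factory=dict)
    r_squared: float = float("nan")


def fit_growth_rate(tc: TimeCourse, window: tuple[float, float] | None = None
                    ) -> tuple[float, float]:
    """Slope of ln(biomass) vs time; returns (mu, R^2).

    ``window`` restricts the fit to times within [t0, t1] (inclusive);
    at least three points are required.
    """
    t = tc.times
    x = tc.biomass
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, x = t[mask], x[mask]
    if len(t) < 3:
        raise ValueError("growth-rate fit needs at least 3 points")
    if np.any(x <= 0):
        raise ValueError("biomass must be positive for the log fit")
    fit = stats.linregress(t, np.log(x))
    return float(fit.slope), float(fit.rvalue**2)


def specific_rate_growth(mu: float, c_m_start: float, c_m_end: float,
                         c_x_start: float, c_x_end: float) -> float:
    """r_M = mu (c_M,e - c_M,s)/(c_X,e - c_X,s), mmol/gDW/h.

    Positive for products, negative for consumed substrates; the table
    layer reports uptake as a positive magnitude.
    """
    dx = c_x_end - c_x_start
    if dx == 0:
        raise ValueError(
            "no biomass change: use the growth-arrest formula "
            "(specific_rate_arrest)"
        )
    return mu * (c_m_end - c_m_start) / dx


def specific_rate_arrest(c_m_start: float, c_m_end: float,
                         x_avg: float, dt: float) -> float:
    """r_M = (c_M,e - c_M,s)/X_av/dt for constant-biomass cultures."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if x_avg <= 0:
        raise ValueError("average biomass must be > 0")
    return (c_m_end - c_m_start) / x_avg / dt


def yield_regression(tc: TimeCourse, analyte: str,
                     reference: str = "glc") -> float:
    """Yield as the regression slope of dc_analyte against dc_glucose.

    Both deltas are taken relative to the first sample; glucose deltas are
    signed so that consumption is positive (yields come out positive for
    products).  The biomass variant uses gDW/l against g/l of glucose.
    """
    d_ref = tc.concentration(reference)[0] - tc.concentration(reference)
    if analyte == "biomass":
        d_m = tc.biomass - tc.biomass[0]
        d_ref = d_ref * 0.18016  # mmol/l -> g/l glucose
    else:
        d_m = tc.concentration(analyte) - tc.concentration(analyte)[0]
    if len(d_ref) < 3:
        raise ValueError("yield regression needs at least 3 points")
    if np.max(d_ref) <= 0:
        raise ValueError("no glucose consumed")
    if np.allclose(d_m, 0):
        return 0.0
    fit = stats.linregress(d_ref, d_m)
    return float(fit.slope)


def percent_change(value: float, reference: float) -> float:
    """100 * (value - reference)/reference."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (value - reference) / reference


def carbon_yield(yields: dict[str, float]) -> float:
    """Cumulated product carbon per glucose carbon.

    ``yields`` maps analyte (eth/ace/for/lac/suc) to mol product per mol
    glucose; the result is sum(Y_i * C_i)/6.
    """
    missing = [a for a in CARBON_ATOMS if a not in yields]
    if missing:
        raise ValueError(f"missing yields for: {', '.join(sorted(missing))}")
    return sum(yields[a] * c for a, c in CARBON_ATOMS.items()) / 6.0


def rates_from_timecourse(tc: TimeCourse, mode: str = "growth",
                          window: tuple[float, float] | None = None
                          ) -> RateSummary:
    """Full rate/yield summary of one culture time course.

    ``mode='growth'`` uses the exponential-phase formulas (endpoints of the
    window), ``mode='arrest'`` the constant-biomass formulas with the time-
    averaged biomass.
    """
    t = tc.times
    if window is None:
        window = (t[0], t[-1])
    mask = (t >= window[0]) & (t <= window[1])
    idx = np.where(mask)[0]
    if len(idx) < 3:
        raise ValueError("window must contain at least 3 samples")
    i0, i1 = idx[0], idx[-1]

    rates: dict[str, float] = {}
    yields: dict[str, float] = {}
    if mode == "growth":
        mu, r2 = fit_growth_rate(tc, window)
        for a in tc.analytes:
            c = tc.concentration(a)
            rates[a] = specific_rate_growth(
                mu, c[i0], c[i1], tc.biomass[i0], tc.biomass[i1])
    elif mode == "arrest":
        mu, r2 = 0.0, float("nan")
        x_avg = float(np.mean(tc.biomass[mask]))
        dt = t[i1] - t[i0]
        for a in tc.analytes:
            c = tc.concentration(a)
            rates[a] = specific_rate_arrest(c[i0], c[i1], x_avg, dt)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for a in tc.analytes:
        if a != "glc":
            yields[a] = yield_regression(tc, a)
    return RateSummary(mu=mu, rates=rates, yields=yields, r_squared=r2)
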