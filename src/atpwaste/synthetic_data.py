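"""Synthetic fermentation cultures with the structure the analysis assumes.

Forward mass balances of a batch culture: dX/dt = mu X and
dc_M/dt = +/- r_M X with constant specific rates, which integrate to

    growth:  X(t) = X0 e^(mu t),  c_M(t) = c_M0 +/- (r_M/mu)(X(t) - X0)
    arrest:  X(t) = X0,           c_M(t) = c_M0 +/- r_M X0 t

Glucose is clamped at zero once exhausted and all conversion ceases.
Measurement noise mimics the two instruments: multiplicative lognormal on
biomass (OD-like) and additive truncated Gaussian on the HPLC
concentrations.  Default generating values are the measured strain rates
bundled with the package, so that the rate/yield arithmetic, the MFA
pipeline and the noise propagation can be exercised end to end without
any external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import load_rate_table
from .rates import TimeCourse

__all__ = [
    "StrainProfile",
    "simulate_culture",
    "make_rate_table",
    "perturb_parameters",
    "table_profile",
    "list_profiles",
    "DEFAULT_NOISE",
]

#: default measurement noise: 2% relative on biomass, 0.1 mmol/l on
#: concentrations
DEFAULT_NOISE = {"sigma_biomass_rel": 0.02, "sigma_conc_abs": 0.1}

#: initial conditions mirroring the cultivation protocol: OD420 0.2
#: (0.044 gDW/l) for growth, OD420 2.0 (0.44 gDW/l) for growth arrest,
#: 4 g/l glucose (22.2 mmol/l)
X0_GROWTH = 0.044
X0_ARREST = 0.44
GLC0 = 22.2

PRODUCTS = ["eth", "ace", "for", "lac", "suc"]


@dataclass
class StrainProfile:
    """Generating parameters of one synthetic culture."""

    label: str
    mu_true: float                      # 1/h
    r_true: dict[str, float]            # mmol/gDW/h; glc = uptake (> 0)
    mode: str = "growth"                # 'growth' | 'arrest'
    x0: float = X0_GROWTH               # gDW/l
    glc0: float = GLC0                  # mmol/l

    def __post_init__(self):
        if self.mode not in ("growth", "arrest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mu_true < 0:
            raise ValueError("mu_true must be >= 0")
        if self.mode == "arrest" and self.mu_true != 0:
            raise ValueError("growth arrest implies mu_true = 0")
        if self.r_true.get("glc", 0.0) < 0:
            raise ValueError("glucose uptake rate must be >= 0")
        for a in PRODUCTS:
            if self.r_true.get(a, 0.0) < 0:
                raise ValueError(f"production rate of {a} must be >= 0")


def _closed_form(profile: StrainProfile, t: np.ndarray):
    """Noiseless biomass and concentration trajectories."""
    mu = profile.mu_true
    x0 = profile.x0
    r_glc = profile.r_true.get("glc", 0.0)

    # glucose exhaustion time (conversion stops there)
    if r_glc > 0:
        if profile.mode == "growth" and mu > 0:
            # glc0 = (r/mu)(X - X0)  =>  X_exh
            x_exh = x0 + profile.glc0 * mu / r_glc
            t_exh = np.log(x_exh / x0) / mu
        elif profile.mode == "arrest":
            t_exh = profile.glc0 / (r_glc * x0)
        else:  # mu == 0 in growth mode: nothing happens
            t_exh = np.inf
    else:
        t_exh = np.inf

    te = np.minimum(t, t_exh)
    if profile.mode == "growth" and mu > 0:
        x = x0 * np.exp(mu * t)
        consumed = (r_glc / mu) * (x0 * np.exp(mu * te) - x0)

        def produced(r):
            return (r / mu) * (x0 * np.exp(mu * te) - x0)
    else:
        x = np.full_like(t, x0)
        consumed = r_glc * x0 * te

        def produced(r):
            return r * x0 * te

    conc = {"glc": np.maximum(profile.glc0 - consumed, 0.0)}
    for a in PRODUCTS:
        conc[a] = produced(profile.r_true.get(a, 0.0))
    return x, conc, t_exh


def simulate_culture(profile: StrainProfile, sample_times,
                     noise: dict | None = None,
                     seed: int | None = None) -> TimeCourse:
    """Sample a synthetic culture at ``sample_times`` (hours).

    With ``noise=None`` or zero noise the samples equal the closed-form
    solutions exactly, so the rate/yield estimators can be validated
    against the generating values to numerical precision.
    """
    t = np.asarray(sample_times, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("sample_times must be strictly increasing")
    noise = {**DEFAULT_NOISE, **(noise or {})}
    if min(noise.values()) < 0:
        raise ValueError("noise levels must be >= 0")

    x, conc, t_exh = _closed_form(profile, t)
    if len(t) > 1 and t_exh < t[1]:
        warnings.warn(
            f"profile {profile.label!r} exhausts glucose at "
            f"t = {t_exh:.2f} h, before the second sample", stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    sb = noise["sigma_biomass_rel"]
    sc = noise["sigma_conc_abs"]
    if sb > 0:
        x = x * rng.lognormal(mean=0.0, sigma=sb, size=len(t))
    if sc > 0:
        conc = {a: np.maximum(c + rng.normal(0.0, sc, size=len(t)), 0.0)
                for a, c in conc.items()}

    df = pd.DataFrame({"time_h": t, "biomass_gDW_l": x, **conc})
    return TimeCourse(df)


def table_profile(strain: str, condition: str = "growth") -> StrainProfile:
    """Profile whose generating values are a bundled measured-rate row."""
    row = load_rate_table(condition).loc[strain]
    r_true = {"glc": float(row.r_glc)}
    for a in PRODUCTS:
        r_true[a] = float(row[f"r_{a}"])
    mode = "arrest" if condition == "arrest" else "growth"
    return StrainProfile(
        label=f"{strain}_{condition}",
        mu_true=0.0 if mode == "arrest" else float(row.mu),
        r_true=r_true,
        mode=mode,
        x0=X0_ARREST if mode == "arrest" else X0_GROWTH,
    )


def list_profiles() -> list[str]:
    out = []
    for condition in ("growth", "arrest"):
        for strain in load_rate_table(condition).index:
            out.append(f"{strain}:{condition}")
    return out


def _carbon_feasible(profile: StrainProfile) -> bool:
    """Crude mass-balance screen: product + biomass carbon <= glucose carbon.

    Biomass carbon uses ~40 mmol C per gDW; a 2% tolerance absorbs
    rounding of the generating rates.
    """
    carbons = {"eth": 2, "ace": 2, "for": 1, "lac": 3, "suc": 4}
    r_glc = profile.r_true.get("glc", 0.0)
    if r_glc <= 0:
        return all(profile.r_true.get(a, 0) == 0 for a in carbons)
    c_out = sum(profile.r_true.get(a, 0.0) * c for a, c in carbons.items())
    c_out += 40.0 * profile.mu_true
    return c_out <= 6.0 * r_glc * 1.02


def make_rate_table(profiles: list[StrainProfile],
                    noise_sd_rel: float = 0.03,
                    n_replicates: int = 3,
                    seed: int | None = None) -> pd.DataFrame:
    """Replicate rate table drawn around the generating rates.

    Per strain, ``n_replicates`` replicate rate sets are drawn with
    relative Gaussian noise, then averaged; columns mirror the bundled
    measured-rate tables plus a ``feasible`` carbon-balance flag.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for p in profiles:
        quantities = {"mu": p.mu_true,
                      **{f"r_{a}": p.r_true.get(a, 0.0)
                         for a in ["glc"] + PRODUCTS}}
        row: dict = {"strain": p.label, "feasible": _carbon_feasible(p)}
        for key, true in quantities.items():
            reps = true * (1.0 + noise_sd_rel *
                           rng.standard_normal(n_replicates)) \
                if noise_sd_rel > 0 else np.full(n_replicates, true)
            row[key] = float(np.mean(reps))
            row[f"{key}_sd"] = float(np.std(reps, ddof=1)) \
                if n_replicates > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("strain")


def perturb_parameters(model, decades: float, seed: int | None = None):
    """Log-uniform Km multipliers over ``decades`` total, per parameter.

    Returns a deep-copied model with every Michaelis constant scaled by
    10^u, u ~ U(-decades/2, +decades/2); decades = 0 is the identity.
    """
    if decades < 0:
        raise ValueError("decades must be >= 0")
    rng = np.random.default_rng(seed)
    pert = model.copy()
    half = decades / 2.0
    for params in pert.parameters.values():
        for sid in params.get("km", {}):
            params["km"][sid] *= 10.0 ** rng.uniform(-half, half)
    return pert
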