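"""Stoichiometric metabolic flux analysis with ATP-maintenance maximization.

The ATPase flux enforced in the overexpression strains cannot be measured
directly; it is estimated stoichiometrically.  Unspecific ATP hydrolysis is
represented by an ATPM pseudo-reaction.  Given the measured specific
exchange rates and growth rate of a strain, the remaining degrees of
freedom of the network are resolved by assuming the cell extracts the
maximum amount of ATP (linear program maximizing the ATPM flux).  The
enforced ATPase flux of an overexpression strain is then the difference
between its maximized ATPM flux and that of its empty-plasmid control:

    r_ATPase = ATPM(ATPase strain) - ATPM(control strain)

Measured rate sets are frequently mutually inconsistent (carbon/redox
balances); they are first minimally adjusted by an SD-weighted
least-squares reconciliation subject to network feasibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, minimize

__all__ = [
    "StoichModel",
    "MFAResult",
    "MFAError",
    "build_default_stoich_model",
    "reconcile_rates",
    "maximize_atpm",
    "atpase_flux",
    "run_mfa",
]

#: mapping from rate-table columns to the model reactions that carry them
#: (boundary metabolites are external, so fixing these reaction fluxes
#: fixes the exchanges; all are positive as printed in the tables)
MEASURED_REACTIONS = {
    "r_glc": "PTS",
    "r_eth": "ADHE",
    "r_ace": "ACK",
    "r_for": "PFL",
    "r_lac": "LDH",
    "r_suc": "FRD",
    "mu": "GROWTH",
}

BIG = 1e4


class MFAError(RuntimeError):
    pass


@dataclass
class StoichModel:
    """Stoichiometric network for LP-based flux analysis.

    ``matrix`` has one row per internal (balanced) metabolite and one
    column per reaction; ``lb``/``ub`` are flux bounds (irreversible
    reactions have lb = 0); ``atpm_id`` names the ATP-hydrolysis
    pseudo-reaction; ``measured`` maps measurement keys to reaction ids.
    """

    matrix: np.ndarray
    metabolite_ids: list[str]
    reaction_ids: list[str]
    lb: np.ndarray
    ub: np.ndarray
    atpm_id: str = "ATPM"
    measured: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        n_met, n_rxn = self.matrix.shape
        assert len(self.metabolite_ids) == n_met
        assert len(self.reaction_ids) == n_rxn

    def index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    @property
    def reduced_matrix(self) -> np.ndarray:
        """Row-independent submatrix (conserved-moiety rows dropped)."""
        from scipy.linalg import qr

        rank = np.linalg.matrix_rank(self.matrix, tol=1e-10)
        _, _, piv = qr(self.matrix.T, pivoting=True)
        return self.matrix[np.sort(piv[:rank])]


@dataclass
class MFAResult:
    reconciled: dict[str, float]
    adjustments: dict[str, float]
    atpm_flux: float
    fluxes: dict[str, float]
    lp_status: str


def build_default_stoich_model() -> StoichModel:
    """Central anaerobic E. coli metabolism with an ATPM pseudo-reaction.

    The network is the kinetic model's stoichiometry with the two ATP-
    hydrolysis reactions (maintenance and ATPase) merged into a single
    ATPM column, so that the LP objective absorbs all unexplained ATP
    turnover, as in standard metabolic flux analysis.
    """
    from .calibrate import IRREVERSIBLE, REFERENCE_CONC, reaction_definitions

    internal = list(REFERENCE_CONC)
    reactions = [r for r in reaction_definitions()
                 if r["id"] not in ("NGAM", "ATPASE")]
    reactions.append({
        "id": "ATPM",
        "stoichiometry": {"ATP": -1, "ADP": 1, "PI": 1},
        "reversible": False,
    })
    rids = [r["id"] for r in reactions]
    idx = {m: i for i, m in enumerate(internal)}
    S = np.zeros((len(internal), len(reactions)))
    for j, rxn in enumerate(reactions):
        for sid, coeff in rxn["stoichiometry"].items():
            if sid in idx:
                S[idx[sid], j] = coeff
    lb = np.full(len(rids), -BIG)
    ub = np.full(len(rids), BIG)
    for rid in IRREVERSIBLE + ["ATPM"]:
        if rid in rids:
            lb[rids.index(rid)] = 0.0
    return StoichModel(
        matrix=S, metabolite_ids=internal, reaction_ids=rids,
        lb=lb, ub=ub, atpm_id="ATPM", measured=dict(MEASURED_REACTIONS),
    )


def _measured_vector(model: StoichModel, measured: dict) -> tuple[list, list, list]:
    keys, js, vals, sds = [], [], [], []
    for key, rid in model.measured.items():
        if key not in measured:
            continue
        sd = float(measured.get(f"{key}_sd", 0.0) or 0.0)
        if sd < 0:
            raise ValueError(f"negative SD for {key}")
        keys.append(key)
        js.append(model.index(rid))
        vals.append(float(measured[key]))
        sds.append(max(sd, 1e-3))  # floor: zero-SD entries stay finite
    return keys, js, np.array(vals), np.array(sds)


def reconcile_rates(model: StoichModel, measured: dict,
                    growth_arrest: bool | None = None) -> MFAResult:
    """SD-weighted minimal adjustment onto the feasible flux cone.

    ``measured`` maps the keys in ``model.measured`` (r_glc, r_eth, ...,
    mu) to values (positive, as printed) with optional ``<key>_sd``
    entries.  Returns an :class:`MFAResult` whose ``reconciled``/
    ``adjustments`` describe the fitted rates; its ``atpm_flux`` is not yet
    maximized (see :func:`maximize_atpm`).
    """
    keys, js, vals, sds = _measured_vector(model, measured)
    if not keys:
        raise ValueError("no recognized measurements provided")
    if growth_arrest is None:
        growth_arrest = abs(measured.get("mu", 0.0)) < 1e-9

    S = model.matrix
    Sr = model.reduced_matrix
    lb, ub = model.lb.copy(), model.ub.copy()
    if growth_arrest and "GROWTH" in model.reaction_ids:
        j = model.index("GROWTH")
        lb[j] = ub[j] = 0.0

    n = S.shape[1]
    w = 1.0 / sds

    def obj(v):
        return float(np.sum((w * (v[js] - vals)) ** 2))

    def grad(v):
        g = np.zeros(n)
        g[js] = 2.0 * w**2 * (v[js] - vals)
        return g

    v0 = np.zeros(n)
    v0[js] = vals
    # project the start into the null space for a feasible-ish seed
    cons = [{"type": "eq", "fun": lambda v: Sr @ v,
             "jac": lambda v: Sr}]
    sol = minimize(obj, v0, jac=grad, method="SLSQP", constraints=cons,
                   bounds=list(zip(lb, ub)),
                   options={"maxiter": 500, "ftol": 1e-12})
    if not sol.success:
        raise MFAError(f"reconciliation failed: {sol.message}")
    v = sol.x
    feas = float(np.max(np.abs(S @ v)))
    if feas > 1e-6:
        raise MFAError(f"reconciliation infeasible (|Sv| = {feas:.2e})")
    reconciled = {k: float(v[j]) for k, j in zip(keys, js)}
    adjustments = {k: float(v[j] - val)
                   for k, j, val in zip(keys, js, vals)}
    return MFAResult(
        reconciled=reconciled, adjustments=adjustments,
        atpm_flux=float(v[model.index(model.atpm_id)]),
        fluxes={rid: float(x) for rid, x in zip(model.reaction_ids, v)},
        lp_status="reconciled",
    )


def maximize_atpm(model: StoichModel, reconciled: dict,
                  growth_arrest: bool | None = None) -> MFAResult:
    """LP maximum of the ATPM flux with the reconciled rates fixed."""
    if growth_arrest is None:
        growth_arrest = abs(reconciled.get("mu", 0.0)) < 1e-9
    S = model.matrix
    n = S.shape[1]
    lb, ub = model.lb.copy(), model.ub.copy()
    for key, rid in model.measured.items():
        if key in reconciled:
            j = model.index(rid)
            lb[j] = ub[j] = float(reconciled[key])
    if growth_arrest and "GROWTH" in model.reaction_ids:
        j = model.index("GROWTH")
        lb[j] = ub[j] = 0.0
    Sr = model.reduced_matrix
    c = np.zeros(n)
    c[model.index(model.atpm_id)] = -1.0
    res = linprog(c, A_eq=Sr, b_eq=np.zeros(Sr.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status == 3:
        raise MFAError(
            "ATPM maximization unbounded: an energy-generating cycle is "
            "missing a bound"
        )
    if not res.success:
        raise MFAError(f"ATPM maximization failed: {res.message}")
    v = res.x
    return MFAResult(
        reconciled=dict(reconciled), adjustments={},
        atpm_flux=float(v[model.index(model.atpm_id)]),
        fluxes={rid: float(x) for rid, x in zip(model.reaction_ids, v)},
        lp_status="optimal",
    )


def atpase_flux(atpm_strain: float, atpm_control: float) -> float:
    """Enforced ATP-hydrolysis rate: ATPM(strain) - ATPM(control).

    A negative difference is reported as-is with a warning (it indicates
    the control turned over more unexplained ATP than the strain).
    """
    if atpm_strain < 0 or atpm_control < 0:
        raise ValueError("ATPM fluxes must be >= 0")
    diff = atpm_strain - atpm_control
    if diff < 0:
        warnings.warn(
            f"negative ATPase flux ({diff:.3f} mmol/gDW/h): control ATPM "
            "exceeds strain ATPM", stacklevel=2,
        )
    return diff


def run_mfa(model: StoichModel, measured: dict,
            growth_arrest: bool | None = None) -> MFAResult:
    """Reconcile a measured rate set, then maximize ATPM."""
    rec = reconcile_rates(model, measured, growth_arrest=growth_arrest)
    res = maximize_atpm(model, rec.reconciled, growth_arrest=growth_arrest)
    res.adjustments = rec.adjustments
    return res


def strain_atpm(condition: str, strain: str) -> float:
    """Maximized ATPM flux (mmol/gDW/h) for a bundled strain rate row."""
    from .datasets import load_rate_table

    row = load_rate_table(condition).loc[strain]
    measured = {}
    for key in list(MEASURED_REACTIONS):
        measured[key] = float(row[key])
        sd = row.get(f"{key}_sd")
        if sd is not None:
            measured[f"{key}_sd"] = float(sd)
    model = build_default_stoich_model()
    return run_mfa(model, measured,
                   growth_arrest=(condition == "arrest")).atpm_flux
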