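"""Steady-state simulation and ATPase-expression response scans.

A steady state is found by stiff ODE integration to large time followed by a
Newton root-polish in logarithmic coordinates on the moiety-reduced system
(pure Newton from cold starts diverges for this stiff allosteric network;
the integration provides a basin-interior start).  The ATPase scan solves a
sequence of steady states by continuation, reproducing the steady-state
response curves of glucose uptake, energy charge and ATPase flux as the
ATPase expression level (vmax of the ATPase reaction) rises from 0 to a
maximal value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space, qr
from scipy.optimize import root

from .kinetics import EvaluationError, RateEvaluator, activation_term
from .model_core import FLUX_TO_CONC, KineticModel, stoichiometric_matrix

__all__ = [
    "SteadyState",
    "ScanResult",
    "PreconditionError",
    "IntegrationError",
    "energy_charge",
    "integrate_to_steady_state",
    "scan_atpase",
    "is_biphasic",
]

DEFAULT_TOL_SS = 1e-8  # mmol/gDW/h
DEFAULT_T_MAX = 50.0  # h


class PreconditionError(ValueError):
    """Initial state violates a model precondition (e.g. moiety total)."""


class IntegrationError(RuntimeError):
    """The ODE right-hand side could not be evaluated."""


def energy_charge(conc) -> float:
    """Adenylate energy charge ([ATP] + 0.5[ADP]) / ([ATP]+[ADP]+[AMP])."""
    atp, adp, amp = conc["ATP"], conc["ADP"], conc["AMP"]
    if atp < 0 or adp < 0 or amp < 0:
        raise ValueError("adenylate concentrations must be >= 0")
    total = atp + adp + amp
    if total == 0:
        raise ValueError("energy charge undefined: ATP+ADP+AMP = 0")
    return (atp + 0.5 * adp) / total


@dataclass
class SteadyState:
    concentrations: dict[str, float]
    fluxes: dict[str, float]
    residual: float
    converged: bool
    x: np.ndarray = field(repr=False, default=None)
    v: np.ndarray = field(repr=False, default=None)

    @property
    def energy_charge(self) -> float:
        return energy_charge(self.concentrations)


@dataclass
class ScanResult:
    grid: np.ndarray
    states: list[SteadyState]
    clamped_adp_activation: bool

    def flux_curve(self, reaction_id: str) -> np.ndarray:
        return np.array([s.fluxes[reaction_id] for s in self.states])

    @property
    def energy_charges(self) -> np.ndarray:
        return np.array([s.energy_charge for s in self.states])

    @property
    def converged(self) -> np.ndarray:
        return np.array([s.converged for s in self.states])


class _SteadyStateProblem:
    """Moiety-reduced steady-state system for one model instance."""

    def __init__(self, model: KineticModel, evaluator: RateEvaluator):
        self.model = model
        self.evaluator = evaluator
        self.N = stoichiometric_matrix(model)
        n = self.N.shape[0]
        # conservation matrix: declared moieties, completed numerically if
        # the network carries additional (undeclared) conserved pools
        G_rows = [
            np.array([vec.get(sid, 0.0) for sid in model.state_ids])
            for vec in model.moieties.values()
        ]
        rank = np.linalg.matrix_rank(self.N, tol=1e-10)
        n_cons = n - rank
        if len(G_rows) != n_cons:
            G = null_space(self.N.T, rcond=1e-10).T
        else:
            G = np.array(G_rows) if G_rows else np.zeros((0, n))
        self.G = G
        self.rank = rank
        # independent rows of N via QR with column pivoting on N^T
        _, _, piv = qr(self.N.T, pivoting=True)
        self.rows = np.sort(piv[:rank])

    def rhs(self, t, x):
        try:
            v = self.evaluator(x)
        except EvaluationError as exc:
            raise IntegrationError(str(exc)) from exc
        return FLUX_TO_CONC * (self.N @ v)

    def residual(self, x) -> float:
        return float(np.max(np.abs(self.N @ self.evaluator(x))))

    def polish(self, x0, targets):
        """Newton polish in log space; returns (x, success)."""
        x0 = np.maximum(x0, 1e-12)
        u0 = np.log(x0)
        scale = np.maximum(np.abs(targets), 1e-3)

        def fun(u):
            x = np.exp(np.clip(u, -46, 46))
            f1 = (self.N @ self.evaluator(x))[self.rows]
            f2 = (self.G @ x - targets) / scale
            return np.concatenate([f1, f2])

        sol = root(fun, u0, method="hybr",
                   options={"xtol": 1e-12, "maxfev": 120 * len(u0)})
        x = np.exp(np.clip(sol.x, -46, 46))
        return x, bool(sol.success)


def _integrate_burst(problem, x: np.ndarray, t_end: float,
                     max_steps: int = 1500) -> tuple[np.ndarray, bool]:
    """Advance the ODE by up to ``t_end`` hours with a bounded step budget.

    Returns the final state and whether ``t_end`` was actually reached.
    """
    from scipy.integrate import LSODA

    solver = LSODA(problem.rhs, 0.0, x, t_end, rtol=1e-7, atol=1e-9)
    for _ in range(max_steps):
        if solver.status != "running":
            break
        try:
            solver.step()
        except Exception:
            break
    return np.maximum(solver.y, 1e-12), solver.status == "finished"


def _check_preconditions(model: KineticModel, x0: np.ndarray) -> None:
    if np.any(x0 <= 0):
        bad = model.state_ids[int(np.argmax(x0 <= 0))]
        raise PreconditionError(
            f"initial concentration of {bad} must be strictly positive"
        )
    for name, vec in model.moieties.items():
        row = np.array([vec.get(sid, 0.0) for sid in model.state_ids])
        total = float(row @ x0)
        want = model.moiety_totals.get(name)
        if want and abs(total - want) > 1e-6 * abs(want):
            raise PreconditionError(
                f"initial state violates moiety total {name!r}: "
                f"{total:.6g} != {want:.6g}"
            )


def integrate_to_steady_state(
    model: KineticModel,
    x0: np.ndarray | dict | None = None,
    tol_ss: float = DEFAULT_TOL_SS,
    t_max: float = DEFAULT_T_MAX,
    clamp_adp_activation: float | None = None,
    check_moieties: bool = True,
) -> SteadyState:
    """Relax the ODE system to steady state and polish with Newton.

    Non-convergence within ``t_max`` yields a flagged (converged=False)
    state, not an exception.
    """
    evaluator = RateEvaluator(model, clamp_adp_activation)
    problem = _SteadyStateProblem(model, evaluator)
    if x0 is None:
        x0 = model.reference_concentrations()
    elif isinstance(x0, dict):
        x0 = np.array([x0[sid] for sid in model.state_ids])
    else:
        x0 = np.asarray(x0, dtype=float)
    if check_moieties:
        _check_preconditions(model, x0)
    targets = problem.G @ x0

    x = x0
    # Newton attempt straight from x0 (cheap when continuing a scan),
    # otherwise alternate integration bursts with Newton polishing; the
    # per-burst step budget bounds the cost of pathological points (e.g.
    # beyond a fold where only a boundary "metabolic halt" state remains),
    # which are then returned flagged instead of hanging
    t_done = 0.0
    burst = 0.03
    while True:
        x_try, ok = problem.polish(x, targets)
        if ok and problem.residual(x_try) <= tol_ss and np.all(x_try >= 0):
            x = x_try
            break
        if t_done >= t_max:
            break
        x, reached = _integrate_burst(problem, x, burst)
        t_done += burst
        if not reached:
            t_done = t_max  # solver exhausted its budget: give up early
        if "ATP" in model.state_ids and \
                x[model.state_ids.index("ATP")] < 1e-3:
            # energy collapse: the trajectory fell off the viable branch
            # into the ATP-depleted halt state; report it flagged rather
            # than chasing the slowly-relaxing boundary equilibrium
            t_done = t_max
        burst = min(burst * 10.0, max(t_max - t_done, burst))

    v = evaluator(x)
    residual = float(np.max(np.abs(problem.N @ v)))
    converged = residual <= tol_ss and bool(np.all(x >= 0))
    conc = {sid: float(c) for sid, c in zip(model.state_ids, x)}
    conc.update(model.boundary_concentrations())
    fluxes = {rid: float(val) for rid, val in zip(model.reaction_ids, v)}
    return SteadyState(
        concentrations=conc, fluxes=fluxes, residual=residual,
        converged=converged, x=x, v=v,
    )


def wild_type_adp_activation(model: KineticModel,
                             tol_ss: float = DEFAULT_TOL_SS) -> float:
    """Value of the PFK ADP-activation term at the vmax_atpase = 0 state."""
    wt = model.copy()
    wt.vmax_atpase = 0.0
    state = integrate_to_steady_state(wt, tol_ss=tol_ss)
    params = model.parameters["PFK"]
    return activation_term(
        state.concentrations["ADP"], params["ka"]["ADP"],
        params.get("hill", {}).get("ADP", 1.0),
    )


def scan_atpase(
    model: KineticModel,
    grid,
    clamp_adp_activation: bool = False,
    tol_ss: float = DEFAULT_TOL_SS,
) -> ScanResult:
    """Steady-state response over a grid of ATPase expression levels.

    Each grid point is solved by continuation from the previous state.  With
    clamping, the ADP-dependent activation term of PFK is frozen at its
    wild-type (vmax_atpase = 0) value in all solves.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or (len(grid) > 1 and np.any(np.diff(grid) <= 0)):
        raise ValueError("grid must be strictly increasing")
    clamp = wild_type_adp_activation(model, tol_ss) if clamp_adp_activation \
        else None

    states: list[SteadyState] = []
    x_prev = None
    work = model.copy()
    for vm in grid:
        work.vmax_atpase = float(vm)
        state = integrate_to_steady_state(
            work, x0=x_prev, tol_ss=tol_ss,
            clamp_adp_activation=clamp, check_moieties=False,
        )
        states.append(state)
        if state.converged:
            x_prev = state.x
    return ScanResult(grid=grid, states=states,
                      clamped_adp_activation=clamp_adp_activation)


def is_biphasic(curve, margin: float = 0.05) -> bool:
    """Interior maximum with a terminal drop of more than ``margin``.

    Guards against flagging plateaus: the end value must lie below the
    maximum by at least ``margin`` (relative).
    """
    y = np.asarray(curve, dtype=float)
    k = int(np.argmax(y))
    if k == 0 or k == len(y) - 1:
        return False
    return y[-1] < y[k] * (1.0 - margin)
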