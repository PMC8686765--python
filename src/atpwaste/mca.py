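"""Metabolic control analysis with Monte Carlo parameter sampling.

Flux control coefficients (FCCs) quantify the relative change of a
steady-state flux when an enzyme level (vmax) changes:
``C^J_e = (e/J) dJ/de``.  Because every rate law is homogeneous of degree 1
in its vmax, the FCCs over all enzymes of a flux sum to 1 (summation
theorem).

FCCs are computed from elasticities via the control-matrix relations on the
moiety-reduced system (the full Jacobian is structurally singular because
of the conserved adenylate/NAD(H)/CoA/NADP(H)/phosphate pools).  A brute
finite-difference route (re-solving perturbed steady states) is provided as
an independent cross-check.

The Monte Carlo analysis redraws all Michaelis-Menten-type parameters (Km,
Ka, Ki) log-uniformly over two orders of magnitude and rescales each vmax
so the reaction reproduces its reference rate at the reference
concentrations — the sampled models therefore share the exact reference
steady state, and the FCC distributions expose how robust the control
structure is to the (largely unidentifiable) kinetic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import RateEvaluator
from .model_core import KineticModel, stoichiometric_matrix
from .simulate import SteadyState, integrate_to_steady_state

__all__ = [
    "FCCMatrix",
    "FCCSampleSet",
    "compute_fccs",
    "fcc_finite_difference",
    "sample_preserving_steady_state",
    "sign_dominance",
    "predict_enzyme_doubling",
    "reference_state",
]

#: reference fluxes below this magnitude (mmol/gDW/h) give ill-defined
#: scaled FCC rows and are masked
FLUX_FLOOR = 1e-9


@dataclass
class FCCMatrix:
    """Scaled flux control coefficients C[i, j] = C^{J_i}_{e_j}."""

    matrix: np.ndarray
    reaction_ids: list[str]
    reference_state: SteadyState
    reference_label: str = ""

    def get(self, flux: str, enzyme: str) -> float:
        i = self.reaction_ids.index(flux)
        j = self.reaction_ids.index(enzyme)
        return float(self.matrix[i, j])

    def row_sums(self) -> np.ndarray:
        """Per-flux sum over enzymes (1 where defined, NaN where masked)."""
        return np.nansum(self.matrix, axis=1) + np.where(
            np.all(np.isnan(self.matrix), axis=1), np.nan, 0.0
        )


@dataclass
class FCCSampleSet:
    samples: list[FCCMatrix]
    n: int
    seed: int
    reaction_ids: list[str]
    n_resampled: int = 0
    reference_label: str = ""

    def stack(self, flux: str, enzyme: str) -> np.ndarray:
        return np.array([s.get(flux, enzyme) for s in self.samples])

    def sign_fraction(self, flux: str, enzyme: str,
                      sign: int = +1) -> float:
        vals = self.stack(flux, enzyme)
        if sign >= 0:
            return float(np.mean(vals > 0))
        return float(np.mean(vals < 0))


def _elasticities(evaluator: RateEvaluator, x: np.ndarray,
                  rel: float = 1e-6) -> np.ndarray:
    """Unscaled elasticity matrix dv/dx at x (central differences)."""
    n = len(x)
    v0 = evaluator(x)
    E = np.zeros((len(v0), n))
    for i in range(n):
        h = rel * max(abs(x[i]), 1e-4)
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        E[:, i] = (evaluator(xp) - evaluator(xm)) / (2 * h)
    return E


def _control_matrix(N: np.ndarray, E: np.ndarray,
                    rows: np.ndarray) -> np.ndarray:
    """Unscaled flux-control matrix C = I - E L (Nr E L)^-1 Nr."""
    Nr = N[rows]
    L = N @ np.linalg.pinv(Nr)  # link matrix: N = L Nr
    M = Nr @ E @ L
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular Jacobian at the reference state; use the "
            "finite-difference route (fcc_finite_difference)"
        ) from exc
    n_rxn = N.shape[1]
    return np.eye(n_rxn) - E @ L @ Minv @ Nr


def compute_fccs(model: KineticModel, state: SteadyState,
                 reference_label: str = "",
                 evaluator: RateEvaluator | None = None) -> FCCMatrix:
    """Scaled FCC matrix at a converged steady state."""
    if not state.converged:
        raise ValueError("reference state is not converged")
    evaluator = evaluator or RateEvaluator(model)
    N = stoichiometric_matrix(model)
    from .simulate import _SteadyStateProblem

    prob = _SteadyStateProblem(model, evaluator)
    E = _elasticities(evaluator, state.x)
    C = _control_matrix(N, E, prob.rows)
    v = state.v
    scaled = np.full_like(C, np.nan)
    for i in range(len(v)):
        if abs(v[i]) < FLUX_FLOOR:
            continue
        scaled[i, :] = C[i, :] * v / v[i]
    return FCCMatrix(matrix=scaled, reaction_ids=model.reaction_ids,
                     reference_state=state,
                     reference_label=reference_label)


def fcc_finite_difference(model: KineticModel, state: SteadyState,
                          flux: str, enzyme: str,
                          rel: float = 1e-4) -> float:
    """Brute-force FCC: re-solve steady states at vmax * (1 +/- rel)."""
    logj = []
    for fac in (1.0 + rel, 1.0 - rel):
        pert = model.copy()
        pert.parameters[enzyme]["vmax"] *= fac
        st = integrate_to_steady_state(pert, x0=state.x,
                                       check_moieties=False)
        if not st.converged:
            raise RuntimeError(
                f"perturbed steady state ({enzyme} x{fac}) did not converge"
            )
        logj.append(np.log(abs(st.fluxes[flux])))
    return float((logj[0] - logj[1]) / (np.log1p(rel) - np.log1p(-rel)))


def _resample_parameters(model: KineticModel, rng: np.random.Generator,
                         decades: float, conc: dict) -> KineticModel:
    """Draw Km/Ka/Ki multipliers, log-uniform over ``decades`` total.

    For reversible laws the reverse-capacity ratio gamma is co-adjusted so
    that the forward/reverse flux split at the reference concentrations is
    preserved; the redrawn affinities therefore never flip the direction
    of a reaction at the reference state.
    """
    from .kinetics import _saturation

    pert = model.copy()
    half = decades / 2.0
    for rxn in pert.reactions:
        params = pert.parameters[rxn.id]
        km_old = dict(params.get("km", {}))
        # only the Michaelis constants are redrawn; allosteric activation/
        # inhibition constants are structural regulation, not saturation
        # parameters, and are kept at their calibrated values
        for sid in params.get("km", {}):
            params["km"][sid] *= 10.0 ** rng.uniform(-half, half)
        if rxn.reversible and "gamma" in params and km_old:
            order = params.get("order")
            subs = {s: m for s, m in rxn.substrates}
            prods = {s: m for s, m in rxn.products}
            sf_o, _ = _saturation(conc, subs, km_old, rxn.id, order)
            sr_o, _ = _saturation(conc, prods, km_old, rxn.id, order)
            sf_n, _ = _saturation(conc, subs, params["km"], rxn.id, order)
            sr_n, _ = _saturation(conc, prods, params["km"], rxn.id, order)
            if sr_o > 0 and sf_o > 0 and sr_n > 0:
                params["gamma"] *= (sr_o / sf_o) * (sf_n / sr_n)
    return pert


def sample_preserving_steady_state(
    model: KineticModel,
    state: SteadyState,
    n: int,
    seed: int,
    range_decades: float = 2.0,
    reference_label: str = "",
) -> FCCSampleSet:
    """Monte Carlo FCC distributions under steady-state-preserving sampling.

    Each sample redraws the affinity parameters and rescales every vmax so
    the reaction rate at the reference concentrations equals the reference
    flux exactly; the FCCs are then recomputed for the sampled model.
    """
    if not state.converged:
        raise ValueError("reference state is not converged")
    rng = np.random.default_rng(seed)
    v_ref = state.v
    base_v = RateEvaluator(model)(state.x)
    if not np.allclose(base_v, v_ref, rtol=1e-6, atol=1e-9):
        raise ValueError(
            "model does not reproduce the reference state fluxes "
            "(did you forget to set vmax_atpase to the reference value?)"
        )
    conc = dict(state.concentrations)
    samples: list[FCCMatrix] = []
    n_resampled = 0
    while len(samples) < n:
        if n_resampled > 100 * n + 1000:
            raise RuntimeError(
                "steady-state-preserving sampling rejected too many draws"
            )
        pert = _resample_parameters(model, rng, range_decades, conc)
        ev = RateEvaluator(pert)
        v_new = ev(state.x)
        ok = True
        for j, rid in enumerate(pert.reaction_ids):
            if abs(v_ref[j]) < FLUX_FLOOR:
                continue
            if abs(v_new[j]) < 1e-300 or v_ref[j] * v_new[j] <= 0:
                ok = False  # rescaled vmax would be non-positive
                break
            pert.parameters[rid]["vmax"] *= v_ref[j] / v_new[j]
        if not ok:
            n_resampled += 1
            continue
        ev = RateEvaluator(pert)
        assert np.allclose(ev(state.x), v_ref, rtol=1e-9, atol=1e-12)
        samples.append(
            compute_fccs(pert, state, reference_label, evaluator=ev)
        )
    return FCCSampleSet(samples=samples, n=n, seed=seed,
                        reaction_ids=model.reaction_ids,
                        n_resampled=n_resampled,
                        reference_label=reference_label)


def sign_dominance(samples: FCCSampleSet, flux: str, enzyme: str) -> float:
    """Fraction of samples with a positive FCC of ``enzyme`` on ``flux``."""
    return samples.sign_fraction(flux, enzyme, +1)


def predict_enzyme_doubling(model: KineticModel, state: SteadyState,
                            reaction_ids: list[str]) -> dict[str, float]:
    """Steady-state PTS flux after doubling each enzyme's vmax.

    FCCs hold for infinitesimal changes only; this is the finite (2x)
    prediction, re-solved from the reference state.  Non-converged
    re-solves are reported as NaN.
    """
    if not state.converged:
        raise ValueError("reference state is not converged")
    out: dict[str, float] = {}
    for rid in reaction_ids:
        pert = model.copy()
        pert.parameters[rid]["vmax"] *= 2.0
        st = integrate_to_steady_state(pert, x0=state.x,
                                       check_moieties=False)
        out[rid] = st.fluxes["PTS"] if st.converged else float("nan")
    return out


def reference_state(model: KineticModel, label: str,
                    grid=None) -> tuple[KineticModel, SteadyState, float]:
    """Pick the MCA reference steady state for a strain label.

    ``WT`` is the vmax_atpase = 0 state.  For the ATPase strains the scan
    point whose glucose-uptake (PTS) flux is closest to the strain's
    measured uptake rate is used — on the rising branch for LC, nearest the
    maximum for MC, and on the declining branch for HC (the declining
    branch is what distinguishes the high-expression regime).  Returns a
    model copy with vmax_atpase set accordingly, the steady state, and the
    vmax_atpase value.
    """
    from .datasets import load_rate_table
    from .simulate import scan_atpase

    label = label.upper()
    if label == "WT":
        wt = model.copy()
        wt.vmax_atpase = 0.0
        return wt, integrate_to_steady_state(wt), 0.0

    targets = {"LC": "LC_ATPase", "MC": "MC_ATPase", "HC": "HC_ATPase"}
    if label not in targets:
        raise KeyError(f"unknown reference label {label!r}")
    r_glc = float(load_rate_table("growth").loc[targets[label], "r_glc"])
    if grid is None:
        grid = np.arange(0.0, 86.0, 1.0)
    scan = scan_atpase(model, grid)
    conv = scan.converged
    pts = scan.flux_curve("PTS")
    k = int(np.argmax(np.where(conv, pts, -np.inf)))
    if label == "LC":
        idx = np.arange(0, max(k, 1))
    elif label == "MC":
        idx = np.arange(len(grid))
    else:
        idx = np.arange(k + 1, len(grid))
    idx = idx[conv[idx]]
    j = int(idx[np.argmin(np.abs(pts[idx] - r_glc))])
    ref = model.copy()
    ref.vmax_atpase = float(grid[j])
    return ref, scan.states[j], float(grid[j])
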