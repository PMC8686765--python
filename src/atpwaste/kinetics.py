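"""Rate laws: convenience kinetics with multiplicative allosteric terms.

All enzymatic reactions use convenience kinetics (a generalized reversible
Michaelis-Menten law valid for arbitrary stoichiometries), multiplied by
independent hyperbolic/Hill activation and inhibition terms:

    irreversible:  v = vmax * prod_s (c_s/K_s)^m_s / prod_s sum_k (c_s/K_s)^k
                       * prod_a act(c_a) * prod_i inh(c_i)

    reversible:    v = vmax * (S_f - gamma * S_r) / (D_f + D_r - 1) * mods

with ``S_f/S_r`` the forward/reverse saturation numerators, ``D_f/D_r``
their denominators and ``gamma`` the reverse-capacity ratio (vmax_r/vmax_f).
Activation terms are ``c^h/(Ka^h + c^h)``, inhibition terms
``Ki^h/(Ki^h + c^h)``.  Every law is homogeneous of degree 1 in vmax, the
property the metabolic-control summation theorem relies on.

Version-2 specific terms:

* the PFL capacity is scaled by a monotone factor
  ``g(ATP) = g_min + (1 - g_min) * ATP^h/(Kg^h + ATP^h)`` emulating the
  observed lower PFL abundance at low ATP;
* the PYK flux is multiplied by a pyruvate inhibition term
  ``Ki^h/(Ki^h + PYR^h)``.
"""

from __future__ import annotations

import numpy as np

from .model_core import KineticModel, Reaction

__all__ = [
    "EvaluationError",
    "ConfigurationError",
    "convenience_rate",
    "mass_action_rate",
    "pfk_rate",
    "pfl_vmax_modulation",
    "pyk_pyruvate_inhibition",
    "activation_term",
    "inhibition_term",
    "RateEvaluator",
]


class EvaluationError(ValueError):
    """A rate law could not be evaluated (e.g. missing concentration)."""


class ConfigurationError(ValueError):
    """A version-specific term was requested on the wrong model version."""


def activation_term(c: float, ka: float, h: float = 1.0) -> float:
    """Hyperbolic (Hill) activation, in [0, 1)."""
    c = max(c, 0.0)
    return c**h / (ka**h + c**h)


def inhibition_term(c: float, ki: float, h: float = 1.0) -> float:
    """Hyperbolic (Hill) inhibition, in (0, 1]."""
    c = max(c, 0.0)
    return ki**h / (ki**h + c**h)


def _get_conc(conc, sid: str, rxn: str) -> float:
    try:
        return max(float(conc[sid]), 0.0)
    except KeyError:
        raise EvaluationError(
            f"reaction {rxn}: missing concentration for {sid}"
        ) from None


def _saturation(conc, terms: dict[str, float], km: dict[str, float],
                rxn: str, order: dict[str, float] | None = None
                ) -> tuple[float, float]:
    """Numerator product and denominator product for one reaction side.

    Reactants without a Km entry are treated as saturating (their term is
    1); the kinetic order defaults to the stoichiometric multiplicity and
    can be overridden per species via ``order`` (used for lumped reactions
    such as growth, whose stoichiometric coefficients are not kinetic
    orders).
    """
    order = order or {}
    num = 1.0
    den = 1.0
    for sid, m in terms.items():
        if sid not in km:
            continue
        r = _get_conc(conc, sid, rxn) / km[sid]
        mi = order.get(sid, m)
        if mi == int(mi):
            mi = int(mi)
            num *= r**mi
            den *= sum(r**k for k in range(mi + 1))
        else:
            num *= r**mi
            den *= 1.0 + r**mi
    return num, den


def _modifier_factor(params: dict, conc, rxn: str) -> float:
    hill = params.get("hill", {})
    fac = 1.0
    for sid, ka in params.get("ka", {}).items():
        fac *= activation_term(_get_conc(conc, sid, rxn), ka,
                               hill.get(sid, 1.0))
    for sid, ki in params.get("ki", {}).items():
        fac *= inhibition_term(_get_conc(conc, sid, rxn), ki,
                               hill.get(sid, 1.0))
    return fac


def convenience_rate(params: dict, conc, *, substrates: dict[str, float],
                     products: dict[str, float] | None = None,
                     reversible: bool = False,
                     rxn: str = "?",
                     modifier_factor: float | None = None) -> float:
    """Evaluate a convenience-kinetics law.

    ``substrates``/``products`` map species id to (positive) stoichiometric
    multiplicity.  ``modifier_factor`` overrides the allosteric product (used
    for clamping experiments); by default it is computed from ``params``.
    """
    vmax = params["vmax"]
    km = params.get("km", {})
    order = params.get("order", {})
    sf, df = _saturation(conc, substrates, km, rxn, order)
    if reversible:
        gamma = params.get("gamma", 0.0)
        sr, dr = _saturation(conc, products or {}, km, rxn, order)
        core = vmax * (sf - gamma * sr) / (df + dr - 1.0)
    else:
        core = vmax * sf / df
    if modifier_factor is None:
        modifier_factor = _modifier_factor(params, conc, rxn)
    return core * modifier_factor


def mass_action_rate(params: dict, conc, *, substrates: dict[str, float],
                     rxn: str = "?") -> float:
    """Elementary mass-action law v = k * prod c^m (toy networks)."""
    v = params["k"]
    for sid, m in substrates.items():
        v *= _get_conc(conc, sid, rxn) ** m
    return v


def pfk_rate(params: dict, conc, *, clamp_activation: float | None = None
             ) -> float:
    """Phosphofructokinase law: substrates F6P and ATP, ADP activation,
    PEP inhibition.

    The dual role of the adenylates (ATP substrate, ADP allosteric
    activator) makes the rate biphasic in the ADP/(ATP+ADP) ratio at fixed
    total: the activator term rises with ADP while the ATP saturation falls.
    ``clamp_activation`` freezes the ADP term at a given value (used for the
    counterfactual scan without ADP activation).
    """
    atp = _get_conc(conc, "ATP", "PFK")
    adp = _get_conc(conc, "ADP", "PFK")
    if atp + adp <= 0:
        raise EvaluationError("PFK: total ATP+ADP must be > 0")
    hill = params.get("hill", {})
    act = (
        clamp_activation
        if clamp_activation is not None
        else activation_term(adp, params["ka"]["ADP"], hill.get("ADP", 1.0))
    )
    inh = inhibition_term(
        _get_conc(conc, "PEP", "PFK"), params["ki"]["PEP"],
        hill.get("PEP", 1.0),
    )
    return convenience_rate(
        params, conc,
        substrates={"F6P": 1, "ATP": 1},
        rxn="PFK",
        modifier_factor=act * inh,
    )


def pfl_vmax_modulation(params: dict, atp: float, *, version: str = "v2"
                        ) -> float:
    """Effective PFL vmax under the version-2 ATP-dependent capacity term.

    g(ATP) is monotone non-decreasing, g(0) = g_min, g(inf) = 1.
    """
    if version != "v2":
        raise ConfigurationError(
            "PFL vmax modulation is a version-2 term (model is v1)"
        )
    if atp < 0:
        raise EvaluationError("PFL: ATP must be >= 0")
    gmin = params["pfl_gmin"]
    kg = params["pfl_kg"]
    h = params.get("pfl_hg", 1.0)
    g = gmin + (1.0 - gmin) * atp**h / (kg**h + atp**h)
    return params["vmax"] * g


def pyk_pyruvate_inhibition(params: dict, pyr: float, *, version: str = "v2"
                            ) -> float:
    """Version-2 pyruvate inhibition factor for PYK, in (0, 1]."""
    if version != "v2":
        raise ConfigurationError(
            "PYK pyruvate inhibition is a version-2 term (model is v1)"
        )
    ki = params["pyk_ki_pyr"]
    h = params.get("pyk_h_pyr", 1.0)
    return inhibition_term(max(pyr, 0.0), ki, h)


class RateEvaluator:
    """Fast evaluation of the full rate vector v(x) for a model.

    The evaluator owns the mapping from the state vector (non-boundary
    species, umol/gDW) to per-reaction concentration lookups; boundary
    species are read from their clamped reference concentrations.
    """

    def __init__(self, model: KineticModel,
                 clamp_adp_activation: float | None = None):
        self.model = model
        self.clamp_adp_activation = clamp_adp_activation
        self._state_index = {sid: i for i, sid in enumerate(model.state_ids)}
        self._boundary = model.boundary_concentrations()
        self._reactions = list(model.reactions)
        self._params = model.parameters

    def concentrations(self, x: np.ndarray) -> dict[str, float]:
        conc = dict(self._boundary)
        for sid, i in self._state_index.items():
            conc[sid] = x[i]
        return conc

    def reaction_rate(self, rxn: Reaction, conc,
                      enzyme_scale: float = 1.0) -> float:
        params = self._params[rxn.id]
        version = self.model.version
        if rxn.rate_law == "mass_action":
            return enzyme_scale * mass_action_rate(
                params, conc,
                substrates={s: m for s, m in rxn.substrates}, rxn=rxn.id,
            )
        substrates = {s: m for s, m in rxn.substrates}
        products = {s: m for s, m in rxn.products}
        if rxn.id == "PFK":
            v = pfk_rate(params, conc,
                         clamp_activation=self.clamp_adp_activation)
        elif rxn.id == "PFL" and version == "v2":
            vmax_eff = pfl_vmax_modulation(
                params, float(conc["ATP"]), version=version)
            v = convenience_rate(
                {**params, "vmax": vmax_eff}, conc,
                substrates=substrates, products=products,
                reversible=rxn.reversible, rxn=rxn.id,
            )
        elif rxn.id == "PYK" and version == "v2":
            v = convenience_rate(
                params, conc,
                substrates=substrates, products=products,
                reversible=rxn.reversible, rxn=rxn.id,
            ) * pyk_pyruvate_inhibition(
                params, float(conc["PYR"]), version=version)
        else:
            v = convenience_rate(
                params, conc,
                substrates=substrates, products=products,
                reversible=rxn.reversible, rxn=rxn.id,
            )
        return enzyme_scale * v

    def __call__(self, x: np.ndarray,
                 enzyme_scale: dict[str, float] | None = None) -> np.ndarray:
        conc = self.concentrations(np.maximum(x, 0.0))
        scale = enzyme_scale or {}
        v = np.empty(len(self._reactions))
        for j, rxn in enumerate(self._reactions):
            v[j] = self.reaction_rate(rxn, conc, scale.get(rxn.id, 1.0))
        if not np.all(np.isfinite(v)):
            bad = self._reactions[int(np.argmax(~np.isfinite(v)))].id
            raise EvaluationError(f"non-finite rate in reaction {bad}")
        return v
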