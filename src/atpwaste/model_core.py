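"""Network definition and structural validation of the kinetic model.

The model describes the anaerobic central (fermentative) carbon metabolism of
*Escherichia coli*: PTS glucose uptake, glycolysis, the mixed-acid
fermentation branches (formate/acetate/ethanol/lactate), anaplerosis and the
reductive TCA branch to succinate, adenylate kinase, a lumped biomass
(growth) reaction, non-growth-associated maintenance (NGAM) and an ATPase
reaction representing plasmid-borne overexpression of the F1 subunit of the
FoF1-ATP synthase.  The ODE system is ``dx/dt = N v(x, p)`` over the
non-boundary (state) species; external glucose and the secreted products are
clamped boundary species.

Two model versions are supported.  Version 2 differs from version 1 only by
an ATP-dependent down-modulation of the PFL capacity (enzyme-level
regulation at low energy charge) and an allosteric pyruvate inhibition of
pyruvate kinase.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Species",
    "Modifier",
    "Reaction",
    "KineticModel",
    "ModelStructureError",
    "ModelValidationError",
    "build_model",
    "build_default_model",
    "load_default_config",
    "stoichiometric_matrix",
]

#: unit factor between flux units (mmol/gDW/h) and concentration units
#: (umol/gDW): dx/dt [umol/gDW/h] = FLUX_TO_CONC * (N v) [mmol/gDW/h].
#: This is the single place where the two unit systems meet.
FLUX_TO_CONC = 1000.0

DATA_DIR = Path(__file__).parent / "data"


class ModelStructureError(ValueError):
    """A reaction references undeclared species or is otherwise malformed."""


class ModelValidationError(ValueError):
    """Parameters or invariants of the model definition are invalid."""


@dataclass(frozen=True)
class Species:
    id: str
    concentration: float = 0.0  # reference concentration, umol/gDW
    is_boundary: bool = False

    def __post_init__(self):
        if self.concentration < 0:
            raise ModelValidationError(
                f"species {self.id}: concentration must be >= 0"
            )


@dataclass(frozen=True)
class Modifier:
    species: str
    role: str  # 'activator' | 'inhibitor'

    def __post_init__(self):
        if self.role not in ("activator", "inhibitor"):
            raise ModelValidationError(
                f"modifier {self.species}: role must be activator/inhibitor"
            )


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    modifiers: tuple[Modifier, ...] = ()
    rate_law: str = "convenience"  # 'convenience' | 'mass_action'
    reversible: bool = False

    @property
    def substrates(self) -> list[tuple[str, float]]:
        return [(s, -c) for s, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> list[tuple[str, float]]:
        return [(s, c) for s, c in self.stoichiometry.items() if c > 0]


@dataclass
class KineticModel:
    species: list[Species]
    reactions: list[Reaction]
    parameters: dict[str, dict]
    version: str = "v1"
    moieties: dict[str, dict[str, float]] = field(default_factory=dict)
    moiety_totals: dict[str, float] = field(default_factory=dict)

    # -- derived structure (filled by build_model) -----------------------
    _state_ids: list[str] = field(default_factory=list, repr=False)
    _N: np.ndarray | None = field(default=None, repr=False)

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def state_ids(self) -> list[str]:
        """Ids of non-boundary species (the ODE states)."""
        return list(self._state_ids)

    @property
    def boundary_ids(self) -> list[str]:
        return [s.id for s in self.species if s.is_boundary]

    @property
    def n_metabolites(self) -> int:
        """Total metabolite count, boundary species included."""
        return len(self.species)

    @property
    def n_state_species(self) -> int:
        return len(self._state_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def vmax_atpase(self) -> float:
        return self.parameters["ATPASE"]["vmax"]

    @vmax_atpase.setter
    def vmax_atpase(self, value: float) -> None:
        if value < 0:
            raise ModelValidationError("vmax_atpase must be >= 0")
        self.parameters["ATPASE"]["vmax"] = float(value)

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def reaction_by_id(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def reference_concentrations(self) -> np.ndarray:
        """Reference state vector (umol/gDW) over the state species."""
        conc = {s.id: s.concentration for s in self.species}
        return np.array([conc[sid] for sid in self._state_ids])

    def boundary_concentrations(self) -> dict[str, float]:
        return {
            s.id: s.concentration for s in self.species if s.is_boundary
        }

    def copy(self) -> "KineticModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def hash(self) -> str:
        """Deterministic content hash of the model definition."""
        doc = {
            "species": [
                (s.id, s.concentration, s.is_boundary) for s in self.species
            ],
            "reactions": [
                (
                    r.id,
                    sorted(r.stoichiometry.items()),
                    [(m.species, m.role) for m in r.modifiers],
                    r.rate_law,
                    r.reversible,
                )
                for r in self.reactions
            ],
            "parameters": self.parameters,
            "version": self.version,
            "moieties": self.moieties,
        }
        blob = json.dumps(doc, sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()


def _validate_parameters(rxn: Reaction, params: dict) -> None:
    for key in ("vmax", "k"):
        if key in params and params[key] < 0:
            raise ModelValidationError(f"{rxn.id}: {key} must be >= 0")
    for group in ("km", "ka", "ki"):
        for sid, val in params.get(group, {}).items():
            if val <= 0:
                raise ModelValidationError(
                    f"{rxn.id}: {group}[{sid}] must be > 0, got {val}"
                )
    for sid, h in params.get("hill", {}).items():
        if h < 1:
            raise ModelValidationError(
                f"{rxn.id}: hill[{sid}] must be >= 1, got {h}"
            )
    for key in ("gamma", "pfl_gmin", "pfl_kg", "pyk_ki_pyr", "pyk_h_pyr"):
        if key in params and params[key] < 0:
            raise ModelValidationError(f"{rxn.id}: {key} must be >= 0")


def build_model(config: dict | str | Path, version: str = "v1") -> KineticModel:
    """Assemble and validate a :class:`KineticModel` from a config document.

    ``config`` is a mapping (or a path to a YAML file) with keys
    ``species``, ``reactions``, ``parameters`` and optionally ``moieties``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if version not in ("v1", "v2"):
        raise ModelValidationError(f"unknown model version {version!r}")

    species = [
        Species(
            id=s["id"],
            concentration=float(s.get("concentration", 0.0)),
            is_boundary=bool(s.get("is_boundary", False)),
        )
        for s in config["species"]
    ]
    ids = [s.id for s in species]
    if len(set(ids)) != len(ids):
        raise ModelStructureError("species ids are not unique")
    idset = set(ids)

    reactions: list[Reaction] = []
    for r in config["reactions"]:
        stoich = {k: float(v) for k, v in r["stoichiometry"].items()}
        for sid, coeff in stoich.items():
            if sid not in idset:
                raise ModelStructureError(
                    f"reaction {r['id']} references undeclared species {sid}"
                )
            if coeff == 0:
                raise ModelStructureError(
                    f"reaction {r['id']}: zero stoichiometric coefficient "
                    f"for {sid}"
                )
        mods = []
        for m in r.get("modifiers", []):
            if m["species"] not in idset:
                raise ModelStructureError(
                    f"reaction {r['id']} modifier references undeclared "
                    f"species {m['species']}"
                )
            mods.append(Modifier(species=m["species"], role=m["role"]))
        reactions.append(
            Reaction(
                id=r["id"],
                stoichiometry=stoich,
                modifiers=tuple(mods),
                rate_law=r.get("rate_law", "convenience"),
                reversible=bool(r.get("reversible", False)),
            )
        )
    rids = [r.id for r in reactions]
    if len(set(rids)) != len(rids):
        raise ModelStructureError("reaction ids are not unique")

    parameters = {
        rid: {
            k: (dict(v) if isinstance(v, dict) else float(v))
            for k, v in config.get("parameters", {}).get(rid, {}).items()
        }
        for rid in rids
    }
    # version-2 capacity overrides (re-anchored so both versions share the
    # same reference steady state)
    if version == "v2":
        for p in parameters.values():
            if "vmax_v2" in p:
                p["vmax"] = float(p["vmax_v2"])
    for rxn in reactions:
        _validate_parameters(rxn, parameters[rxn.id])

    # every non-boundary species must occur in at least one reaction
    used = set()
    for r in reactions:
        used.update(r.stoichiometry)
    for s in species:
        if not s.is_boundary and s.id not in used:
            raise ModelStructureError(
                f"non-boundary species {s.id} occurs in no reaction"
            )

    model = KineticModel(
        species=species,
        reactions=reactions,
        parameters=parameters,
        version=version,
        moieties={
            name: {k: float(v) for k, v in vec.items()}
            for name, vec in config.get("moieties", {}).items()
        },
    )
    model._state_ids = [s.id for s in species if not s.is_boundary]
    model._N = _assemble_matrix(model)

    # conserved-moiety check via the left null space of N
    N = model._N
    conc = {s.id: s.concentration for s in species}
    for name, vec in model.moieties.items():
        row = np.array(
            [vec.get(sid, 0.0) for sid in model._state_ids]
        )
        resid = np.max(np.abs(row @ N))
        if resid > 1e-9:
            raise ModelValidationError(
                f"moiety {name!r} is not conserved (|m^T N| = {resid:.2e})"
            )
        model.moiety_totals[name] = float(
            sum(vec.get(sid, 0.0) * conc.get(sid, 0.0) for sid in vec)
        )
    return model


def _assemble_matrix(model: KineticModel) -> np.ndarray:
    idx = {sid: i for i, sid in enumerate(model._state_ids)}
    N = np.zeros((len(model._state_ids), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for sid, coeff in r.stoichiometry.items():
            if sid in idx:
                N[idx[sid], j] = coeff
    return N


def stoichiometric_matrix(model: KineticModel) -> np.ndarray:
    """Stoichiometric matrix N (non-boundary species x reactions)."""
    return model._N.copy()


def load_default_config() -> dict:
    """The shipped default network + parameter document."""
    with open(DATA_DIR / "default_model.yaml") as fh:
        return yaml.safe_load(fh)


def build_default_model(version: str = "v1") -> KineticModel:
    """Build the shipped default model (33 metabolites, 28 reactions)."""
    return build_model(load_default_config(), version=version)
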