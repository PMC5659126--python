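"""Domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is a compartmentalised stoichiometric network:
metabolites, bounded reactions (columns of the stoichiometric matrix S),
GPR boolean rules linking reactions to genes, and a registry of
alternative biomass pseudo-reactions of which exactly one is active (has
nonzero bounds and is the objective) at a time.

Flux units throughout are mmol/gCDW/hr; biomass flux is the specific
growth rate in 1/hr.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .gpr import EMPTY_GPR, GPRExpression

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ConstraintSet",
    "ValidationReport",
    "ModelValidationError",
    "DEFAULT_LOWER_BOUND",
    "DEFAULT_UPPER_BOUND",
    "validate_model",
    "set_active_biomass",
]

#: Default flux bounds (COBRA convention) used when a format omits them.
DEFAULT_LOWER_BOUND = -1000.0
DEFAULT_UPPER_BOUND = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    kegg_id: Optional[str] = None
    chebi_id: Optional[str] = None


@dataclass
class Reaction:
    """A bounded stoichiometric reaction.

    ``stoichiometry`` maps metabolite id -> coefficient (negative =
    substrate, positive = product).  An exchange reaction touches exactly
    one metabolite and models transfer across the system boundary;
    negative flux through it is uptake, positive is secretion.
    """

    id: str
    stoichiometry: Dict[str, float]
    name: str = ""
    lower_bound: float = DEFAULT_LOWER_BOUND
    upper_bound: float = DEFAULT_UPPER_BOUND
    gpr: GPRExpression = field(default_factory=lambda: EMPTY_GPR)
    kegg_rxn_id: Optional[str] = None
    is_exchange: bool = False
    is_biomass: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def bounds(self) -> Tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, value: Tuple[float, float]) -> None:
        lb, ub = value
        if lb > ub:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {lb} > upper_bound {ub}"
            )
        self.lower_bound, self.upper_bound = float(lb), float(ub)


class MetabolicModel:
    """A genome-scale (or toy) stoichiometric model."""

    def __init__(
        self,
        model_id: str = "model",
        compartments: Iterable[str] = ("c",),
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective_id: Optional[str] = None,
        biomass_registry: Optional[Dict[str, str]] = None,
    ) -> None:
        self.id = model_id
        self.compartments: List[str] = list(dict.fromkeys(compartments))
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        #: composition id -> biomass reaction id
        self.biomass_registry: Dict[str, str] = dict(biomass_registry or {})
        self.objective_id: Optional[str] = objective_id
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            raise ModelValidationError(
                f"metabolite {met.id!r}: unknown compartment {met.compartment!r}"
            )
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        dangling = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if dangling:
            raise ModelValidationError(
                f"reaction {rxn.id!r} references unknown metabolites: {dangling}"
            )
        self.reactions[rxn.id] = rxn

    def register_biomass(self, composition_id: str, reaction_id: str) -> None:
        if reaction_id not in self.reactions:
            raise KeyError(f"unknown reaction {reaction_id!r}")
        self.reactions[reaction_id].is_biomass = True
        self.biomass_registry[composition_id] = reaction_id

    # -- queries ------------------------------------------------------
    @property
    def genes(self) -> List[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.gpr.genes()
        return sorted(out)

    def reactions_for_gene(self, gene: str) -> List[str]:
        return [r.id for r in self.reactions.values() if gene in r.gpr.genes()]

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, {len(self.genes)} genes>"
        )


@dataclass
class ConstraintSet:
    """Measured exchange rates used to constrain a model.

    Uptake rates are entered as positive magnitudes ``u`` and applied as
    equality bounds ``(-u, -u)`` on the named exchange (chemostat
    measurements fix the rate); secretion rates ``s`` are applied as a
    minimum secretion ``(s, upper)``.  ``dilution_rate`` (1/hr) is carried
    as metadata only.
    """

    uptake: Dict[str, float] = field(default_factory=dict)
    secretion: Dict[str, float] = field(default_factory=dict)
    dilution_rate: Optional[float] = None
    name: str = ""

    def __post_init__(self) -> None:
        for label, rates in (("uptake", self.uptake), ("secretion", self.secretion)):
            for rxn_id, value in rates.items():
                if value < 0:
                    raise ModelValidationError(
                        f"{label} rate for {rxn_id!r} must be >= 0, got {value}"
                    )

    def bounds_map(
        self, secretion_upper: float = DEFAULT_UPPER_BOUND
    ) -> Dict[str, Tuple[float, float]]:
        out: Dict[str, Tuple[float, float]] = {}
        for rxn_id, u in self.uptake.items():
            out[rxn_id] = (-u, -u)
        for rxn_id, s in self.secretion.items():
            out[rxn_id] = (s, secretion_upper)
        return out

    def validate_against(self, model: MetabolicModel) -> None:
        for rxn_id in list(self.uptake) + list(self.secretion):
            if rxn_id not in model.reactions:
                raise KeyError(f"constraint references unknown exchange {rxn_id!r}")
            if not model.reactions[rxn_id].is_exchange:
                raise ModelValidationError(
                    f"constraint target {rxn_id!r} is not an exchange reaction"
                )


@dataclass
class ValidationReport:
    """Structural diagnostics for a model."""

    dead_end_metabolites: List[str]
    blocked_reactions: List[str]
    unreferenced_genes: List[str]

    @property
    def ok(self) -> bool:
        return not self.dead_end_metabolites


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Report dead-end metabolites, fully blocked reactions, orphan genes.

    A dead-end metabolite is one that is produced by no reaction or
    consumed by no reaction, taking reversibility into account: a
    reversible reaction both produces and consumes every metabolite it
    touches.  Reactions with bounds fixed at (0, 0) are ignored for the
    dead-end scan and reported as blocked.
    """
    producers: set[str] = set()
    consumers: set[str] = set()
    blocked: List[str] = []
    for rxn in model.reactions.values():
        if rxn.lower_bound == 0 and rxn.upper_bound == 0:
            blocked.append(rxn.id)
            continue
        forward = rxn.upper_bound > 0
        backward = rxn.lower_bound < 0
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff > 0:
                if forward:
                    producers.add(met_id)
                if backward:
                    consumers.add(met_id)
            elif coeff < 0:
                if forward:
                    consumers.add(met_id)
                if backward:
                    producers.add(met_id)
    dead_ends = sorted(
        m for m in model.metabolites if m not in producers or m not in consumers
    )
    referenced: set[str] = set()
    for rxn in model.reactions.values():
        referenced |= rxn.gpr.genes()
    unreferenced = sorted(set(model.genes) - referenced)
    return ValidationReport(
        dead_end_metabolites=dead_ends,
        blocked_reactions=sorted(blocked),
        unreferenced_genes=unreferenced,
    )


def set_active_biomass(model: MetabolicModel, composition_id: str) -> MetabolicModel:
    """Activate one registered biomass reaction and clamp the others.

    The reaction registered for ``composition_id`` gets bounds (0, 1000)
    and becomes the objective; every other registered biomass reaction is
    clamped to (0, 0).  Modifies and returns ``model``.
    """
    if composition_id not in model.biomass_registry:
        raise KeyError(
            f"unknown biomass composition {composition_id!r}; registered: "
            f"{sorted(model.biomass_registry)}"
        )
    target = model.biomass_registry[composition_id]
    for comp_id, rxn_id in model.biomass_registry.items():
        rxn = model.reactions[rxn_id]
        rxn.bounds = (0.0, DEFAULT_UPPER_BOUND) if rxn_id == target else (0.0, 0.0)
    model.objective_id = target
    return model
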