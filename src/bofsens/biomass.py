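"""Biomass composition data and compilation into biomass pseudo-reactions.

A :class:`BiomassComposition` describes measured cell composition: mass
fractions (g/gDCW) of the five macromolecule pools (protein,
carbohydrate, lipid, RNA, DNA), monomer profiles within each pool (mole
fractions), and the growth-associated ATP maintenance (GAM, mmol
ATP/gDCW).  :func:`build_biomass_reaction` converts this into a drain
reaction on precursor metabolites.

For a macromolecule with mass fraction ``f`` (g/gDCW) and monomer mole
fractions ``x_k``, the monomer drain coefficients are::

    coeff_k = 1000 * f * x_k / sum_k x_k * (MW_k - MW_water)   [mmol/gDCW]

using polymerised-residue weights (each monomer loses one water,
MW_water = 18.02 g/mol, on incorporation), so that the built reaction
drains exactly ``f`` grams of residue mass per gram dry weight.  GAM adds
``gam ATP + gam H2O -> gam ADP + gam Pi``.  The reaction produces one
unit of a biomass pseudo-metabolite; its flux is the specific growth
rate (1/hr).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

from .model import MetabolicModel, ModelValidationError, Reaction

__all__ = [
    "MW_WATER",
    "MonomerSpec",
    "BiomassComposition",
    "DEFAULT_MONOMER_TABLE",
    "build_biomass_reaction",
    "register_compositions",
]

MW_WATER = 18.02

MACRO_POOLS = ("protein", "carbohydrate", "lipid", "RNA", "DNA")


@dataclass(frozen=True)
class MonomerSpec:
    """How one monomer is drained from the network.

    ``mw`` is the free monomer molecular weight (g/mol); the residue
    weight ``mw - MW_WATER`` is used in coefficient arithmetic.
    ``byproducts`` maps metabolite id -> coefficient released per mmol of
    monomer incorporated (e.g. pyrophosphate from NTP polymerisation).
    """

    mw: float
    precursor: str
    byproducts: Mapping[str, float] = field(default_factory=dict)

    @property
    def residue_mw(self) -> float:
        return self.mw - MW_WATER


#: Standard monomer weights (g/mol, free monomers) with conventional
#: cytosolic precursor metabolite ids.  Override per model as needed.
DEFAULT_MONOMER_TABLE: Dict[str, MonomerSpec] = {
    # 20 proteinogenic amino acids
    "ala": MonomerSpec(89.09, "ala_c"),
    "arg": MonomerSpec(174.20, "arg_c"),
    "asn": MonomerSpec(132.12, "asn_c"),
    "asp": MonomerSpec(133.10, "asp_c"),
    "cys": MonomerSpec(121.16, "cys_c"),
    "gln": MonomerSpec(146.15, "gln_c"),
    "glu": MonomerSpec(147.13, "glu_c"),
    "gly": MonomerSpec(75.07, "gly_c"),
    "his": MonomerSpec(155.15, "his_c"),
    "ile": MonomerSpec(131.17, "ile_c"),
    "leu": MonomerSpec(131.17, "leu_c"),
    "lys": MonomerSpec(146.19, "lys_c"),
    "met": MonomerSpec(149.21, "met_c"),
    "phe": MonomerSpec(165.19, "phe_c"),
    "pro": MonomerSpec(115.13, "pro_c"),
    "ser": MonomerSpec(105.09, "ser_c"),
    "thr": MonomerSpec(119.12, "thr_c"),
    "trp": MonomerSpec(204.23, "trp_c"),
    "tyr": MonomerSpec(181.19, "tyr_c"),
    "val": MonomerSpec(117.15, "val_c"),
    # ribonucleoside monophosphates
    "amp": MonomerSpec(347.22, "amp_c"),
    "cmp": MonomerSpec(323.20, "cmp_c"),
    "gmp": MonomerSpec(363.22, "gmp_c"),
    "ump": MonomerSpec(324.18, "ump_c"),
    # deoxyribonucleoside monophosphates
    "damp": MonomerSpec(331.22, "damp_c"),
    "dcmp": MonomerSpec(307.20, "dcmp_c"),
    "dgmp": MonomerSpec(347.22, "dgmp_c"),
    "dtmp": MonomerSpec(322.21, "dtmp_c"),
    # carbohydrate glucose-equivalents and storage polymers
    "glucan": MonomerSpec(180.16, "glucan_c"),
    "glycogen": MonomerSpec(180.16, "glycogen_c"),
    "trehalose": MonomerSpec(360.31, "trehalose_c"),
    # average structural lipid species
    "lipid": MonomerSpec(700.0, "lipid_c"),
}

#: profile key per macromolecule pool
_PROFILE_KEYS = {
    "protein": "protein_profile",
    "carbohydrate": "carb_profile",
    "lipid": "lipid_profile",
    "RNA": "rna_profile",
    "DNA": "dna_profile",
}

PROFILE_SUM_TOL = 1e-6
MACRO_SUM_RANGE = (0.8, 1.05)


@dataclass
class BiomassComposition:
    """Measured composition of one growth condition.

    ``macro_fractions`` in g/gDCW over the five pools; monomer profiles
    are mole fractions summing to 1; ``gam`` in mmol ATP/gDCW.
    ``condition`` carries free-form metadata (aeration, dilution rate,
    carbon-source ratio).
    """

    id: str
    macro_fractions: Dict[str, float]
    gam: float
    protein_profile: Dict[str, float] = field(default_factory=dict)
    carb_profile: Dict[str, float] = field(default_factory=dict)
    lipid_profile: Dict[str, float] = field(default_factory=dict)
    rna_profile: Dict[str, float] = field(default_factory=dict)
    dna_profile: Dict[str, float] = field(default_factory=dict)
    condition: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def profile(self, pool: str) -> Dict[str, float]:
        return getattr(self, _PROFILE_KEYS[pool])

    @property
    def total_mass(self) -> float:
        return sum(self.macro_fractions.values())

    def validate(self) -> None:
        unknown = set(self.macro_fractions) - set(MACRO_POOLS)
        if unknown:
            raise ModelValidationError(
                f"composition {self.id!r}: unknown macromolecule pools {sorted(unknown)}"
            )
        if any(v < 0 for v in self.macro_fractions.values()):
            raise ModelValidationError(
                f"composition {self.id!r}: negative macromolecule fraction"
            )
        total = self.total_mass
        lo, hi = MACRO_SUM_RANGE
        if total > 0 and not (lo <= total <= hi):
            raise ModelValidationError(
                f"composition {self.id!r}: macromolecule fractions sum to "
                f"{total:.3f} g/gDCW, outside [{lo}, {hi}]"
            )
        if self.gam < 0:
            raise ModelValidationError(f"composition {self.id!r}: negative GAM")
        for pool in MACRO_POOLS:
            prof = self.profile(pool)
            frac = self.macro_fractions.get(pool, 0.0)
            if frac > 0 and not prof:
                raise ModelValidationError(
                    f"composition {self.id!r}: pool {pool!r} has mass but no "
                    f"monomer profile"
                )
            if prof:
                s = sum(prof.values())
                if abs(s - 1.0) > PROFILE_SUM_TOL:
                    raise ModelValidationError(
                        f"composition {self.id!r}: {pool} profile sums to {s:.8f}"
                    )
                if any(x < 0 for x in prof.values()):
                    raise ModelValidationError(
                        f"composition {self.id!r}: negative mole fraction in {pool}"
                    )


@dataclass(frozen=True)
class EnergyMetabolites:
    """Metabolite ids used for the GAM term of a biomass reaction."""

    atp: str = "atp_c"
    adp: str = "adp_c"
    pi: str = "pi_c"
    h2o: str = "h2o_c"


def build_biomass_reaction(
    comp: BiomassComposition,
    monomer_table: Mapping[str, MonomerSpec] = DEFAULT_MONOMER_TABLE,
    biomass_metabolite: str = "biomass_c",
    energy: EnergyMetabolites = EnergyMetabolites(),
    reaction_id: Optional[str] = None,
) -> Reaction:
    """Compile a composition into a biomass drain reaction.

    The reaction consumes, per gDCW, ``1000 * f * x_k / sum(x * residue
    MW)`` mmol of each profiled monomer's precursor, plus the GAM ATP
    hydrolysis, and produces 1 unit of the biomass pseudo-metabolite.
    Polymerisation byproducts declared in the monomer table are emitted
    proportionally.
    """
    stoich: Dict[str, float] = {}

    def _add(met: str, coeff: float) -> None:
        stoich[met] = stoich.get(met, 0.0) + coeff

    for pool in MACRO_POOLS:
        frac = comp.macro_fractions.get(pool, 0.0)
        if frac == 0.0:
            continue
        prof = comp.profile(pool)
        missing = sorted(set(prof) - set(monomer_table))
        if missing:
            raise KeyError(
                f"composition {comp.id!r}: monomers {missing} in {pool} profile "
                f"absent from monomer table"
            )
        mean_residue_mw = sum(
            x * monomer_table[m].residue_mw for m, x in prof.items()
        )
        if mean_residue_mw <= 0:
            raise ModelValidationError(
                f"composition {comp.id!r}: non-positive mean residue MW in {pool}"
            )
        for monomer, x in prof.items():
            if x == 0.0:
                continue
            spec = monomer_table[monomer]
            coeff = 1000.0 * frac * x / mean_residue_mw
            _add(spec.precursor, -coeff)
            for met, byp in spec.byproducts.items():
                _add(met, byp * coeff)

    if comp.gam > 0:
        _add(energy.atp, -comp.gam)
        _add(energy.h2o, -comp.gam)
        _add(energy.adp, comp.gam)
        _add(energy.pi, comp.gam)

    _add(biomass_metabolite, 1.0)
    return Reaction(
        id=reaction_id or f"BIOMASS_{comp.id}",
        name=f"biomass formation ({comp.id})",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        is_biomass=True,
    )


def biomass_mass_drained(
    reaction: Reaction,
    monomer_table: Mapping[str, MonomerSpec] = DEFAULT_MONOMER_TABLE,
) -> float:
    """Grams of residue mass drained per unit biomass flux (sanity check).

    Should equal the composition's total macromolecule mass within 1e-6.
    """
    by_precursor = {
        spec.precursor: spec.residue_mw for spec in monomer_table.values()
    }
    total = 0.0
    for met, coeff in reaction.stoichiometry.items():
        if coeff < 0 and met in by_precursor:
            total += -coeff * by_precursor[met] / 1000.0
    return total


def register_compositions(
    model: MetabolicModel,
    compositions: list[BiomassComposition],
    monomer_table: Mapping[str, MonomerSpec] = DEFAULT_MONOMER_TABLE,
    biomass_metabolite: str = "biomass_c",
    energy: EnergyMetabolites = EnergyMetabolites(),
) -> MetabolicModel:
    """Build and register one biomass reaction per composition.

    All registered reactions start clamped to (0, 0); activate one with
    :func:`bofsens.model.set_active_biomass`.
    """
    for comp in compositions:
        rxn = build_biomass_reaction(
            comp, monomer_table, biomass_metabolite, energy
        )
        rxn.bounds = (0.0, 0.0)
        missing = [m for m in rxn.stoichiometry if m not in model.metabolites]
        if missing:
            raise ModelValidationError(
                f"composition {comp.id!r}: precursor metabolites {missing} "
                f"absent from model"
            )
        if rxn.id in model.reactions:
            raise ModelValidationError(f"biomass reaction {rxn.id!r} already exists")
        model.add_reaction(rxn)
        model.register_biomass(comp.id, rxn.id)
    return model
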