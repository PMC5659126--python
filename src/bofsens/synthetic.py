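"""Synthetic toy networks and biomass-composition sets with known truth.

These generators let every pipeline stage be tested end to end without
any external model download.  The core fixture is a deterministic
~40-reaction methylotrophic-yeast-like network: glucose / glycerol /
methanol carbon sources, a respiration-vs-fermentation redox branch
point, arabitol overflow, precursor pathways feeding the five
macromolecule pools, a heterologous-protein drain, and GPR rules
containing essential single-copy genes, isoenzyme pairs, and a
promiscuous gene.  Twelve biomass compositions mirror the structure of
condition-specific composition measurements (aeration series, dilution
rates, glycerol:methanol ratios), and deliberately include one exactly
duplicated pair (a negative control for the significance procedure) and
one strongly contrasting pair.

Ground-truth essential gene sets are established by construction (a
chain gene is the sole route from carbon to an obligatory biomass
precursor), never by the pipeline under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .biomass import (
    BiomassComposition,
    EnergyMetabolites,
    MonomerSpec,
    register_compositions,
)
from .gpr import parse_gpr
from .model import ConstraintSet, MetabolicModel, Metabolite, Reaction, set_active_biomass

__all__ = [
    "FixtureSpec",
    "CORE_MONOMER_TABLE",
    "make_core_fixture",
    "core_constraints",
    "generate_random_network",
    "generate_biomass_set",
]


# ---------------------------------------------------------------------------
# the deterministic core fixture
# ---------------------------------------------------------------------------

#: monomer table for the core fixture's reduced precursor set
CORE_MONOMER_TABLE: Dict[str, MonomerSpec] = {
    "gly": MonomerSpec(75.07, "gly_c"),
    "ala": MonomerSpec(89.09, "ala_c"),
    "glucan": MonomerSpec(180.16, "glucan_c"),
    "glycogen": MonomerSpec(180.16, "glycogen_c"),
    "trehalose": MonomerSpec(360.31, "trehalose_c"),
    "lipid": MonomerSpec(700.0, "lipid_c"),
    "nmp": MonomerSpec(340.0, "nmp_c"),
    "dnmp": MonomerSpec(325.0, "dnmp_c"),
}

#: ids of the deliberately duplicated composition pair (negative control)
DUPLICATE_PAIR = ("wt_normoxic", "fab_normoxic")
#: ids of a strongly contrasting pair (positive control)
CONTRAST_PAIR = ("wt_normoxic", "fab_hypoxic")

#: genes whose single deletion abolishes growth on glucose, by construction
CORE_ESSENTIAL_GENES = frozenset(
    {"g_glk1", "g_shm2", "g_psa1", "g_gsy1", "g_tps1",
     "g_fas1", "g_fas2", "g_ura2", "g_rnr1"}
)


def _core_compositions() -> List[BiomassComposition]:
    """Twelve condition-style compositions (g/gDCW, GAM in mmol/gDCW).

    fab_normoxic repeats wt_normoxic exactly; fab_hypoxic contrasts with
    it strongly (glycine-poor protein, lipid-rich) so that glycine and
    lipid synthesis fluxes shift more than twofold between the two.
    """
    def comp(cid, protein, carb, lipid, rna, dna, gam, gly, tre, **meta):
        return BiomassComposition(
            id=cid,
            macro_fractions={
                "protein": protein, "carbohydrate": carb, "lipid": lipid,
                "RNA": rna, "DNA": dna,
            },
            gam=gam,
            protein_profile={"gly": gly, "ala": round(1.0 - gly, 10)},
            carb_profile={
                "glucan": round(0.85 - tre, 10), "glycogen": 0.15,
                "trehalose": tre,
            },
            lipid_profile={"lipid": 1.0},
            rna_profile={"nmp": 1.0},
            dna_profile={"dnmp": 1.0},
            condition=meta,
        )

    return [
        comp("wt_normoxic", 0.45, 0.25, 0.10, 0.080, 0.012, 30.0, 0.55, 0.05,
             strain="wild-type", aeration="normoxic"),
        comp("wt_oxygen_limited", 0.42, 0.28, 0.09, 0.075, 0.012, 28.0, 0.50,
             0.08, strain="wild-type", aeration="oxygen-limited"),
        comp("wt_hypoxic", 0.40, 0.30, 0.11, 0.065, 0.012, 26.0, 0.40, 0.12,
             strain="wild-type", aeration="hypoxic"),
        comp("fab_normoxic", 0.45, 0.25, 0.10, 0.080, 0.012, 30.0, 0.55, 0.05,
             strain="Fab-producing", aeration="normoxic"),
        comp("fab_oxygen_limited", 0.41, 0.28, 0.10, 0.072, 0.012, 28.5, 0.45,
             0.09, strain="Fab-producing", aeration="oxygen-limited"),
        comp("fab_hypoxic", 0.36, 0.30, 0.15, 0.060, 0.012, 24.0, 0.20, 0.30,
             strain="Fab-producing", aeration="hypoxic"),
        comp("gm80_20_d005", 0.44, 0.26, 0.10, 0.065, 0.012, 31.0, 0.52, 0.06,
             glycerol_methanol="80:20", dilution_rate=0.05),
        comp("gm60_40_d005", 0.43, 0.27, 0.10, 0.066, 0.012, 31.5, 0.50, 0.06,
             glycerol_methanol="60:40", dilution_rate=0.05),
        comp("gm40_60_d005", 0.42, 0.27, 0.11, 0.067, 0.012, 32.0, 0.48, 0.07,
             glycerol_methanol="40:60", dilution_rate=0.05),
        comp("gm80_20_d016", 0.46, 0.23, 0.10, 0.095, 0.013, 33.0, 0.53, 0.05,
             glycerol_methanol="80:20", dilution_rate=0.16),
        comp("gm60_40_d016", 0.45, 0.24, 0.10, 0.096, 0.013, 33.5, 0.51, 0.05,
             glycerol_methanol="60:40", dilution_rate=0.16),
        comp("gm40_60_d016", 0.44, 0.24, 0.11, 0.097, 0.013, 34.0, 0.49, 0.06,
             glycerol_methanol="40:60", dilution_rate=0.16),
    ]


def make_core_fixture() -> Tuple[
    MetabolicModel, List[BiomassComposition], Dict[str, str]
]:
    """Build the deterministic core model, its 12 compositions, and
    ground-truth deletion phenotypes (glucose uptake = 1 convention).

    Returns ``(model, compositions, phenotypes)`` where phenotypes maps
    every gene to ``"viable"`` / ``"inviable"``.
    """
    comp_c = ["e", "c"]
    mets = [Metabolite(m, compartment="e") for m in (
        "glc_e", "gol_e", "meoh_e", "o2_e", "co2_e", "etoh_e", "arab_e", "hsod_e",
    )] + [Metabolite(m, compartment="c") for m in (
        "glc_c", "gol_c", "meoh_c", "o2_c", "co2_c", "etoh_c", "arab_c",
        "pyr_c", "atp_c", "adp_c", "pi_c", "nad_c", "nadh_c", "h2o_c",
        "gly_c", "ala_c", "glucan_c", "glycogen_c", "trehalose_c",
        "lipid_c", "nmp_c", "dnmp_c", "hsod_c", "biomass_c",
    )]

    def rxn(rid, stoich, lb, ub, gpr="", exchange=False, name=""):
        return Reaction(
            id=rid, name=name or rid, stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, gpr=parse_gpr(gpr),
            is_exchange=exchange,
        )

    reactions = [
        # exchanges: carbon sources reversible but capped; products secretion-only
        rxn("EX_glc", {"glc_e": -1}, -10, 1000, exchange=True),
        rxn("EX_gol", {"gol_e": -1}, -10, 1000, exchange=True),
        rxn("EX_meoh", {"meoh_e": -1}, -10, 1000, exchange=True),
        rxn("EX_o2", {"o2_e": -1}, -1000, 1000, exchange=True),
        rxn("EX_co2", {"co2_e": -1}, 0, 1000, exchange=True),
        rxn("EX_etoh", {"etoh_e": -1}, 0, 1000, exchange=True),
        rxn("EX_arab", {"arab_e": -1}, 0, 1000, exchange=True),
        rxn("EX_hsod", {"hsod_e": -1}, 0, 1000, exchange=True),
        rxn("EX_h2o", {"h2o_c": -1}, -1000, 1000, exchange=True),
        # transport (hexose transporter isoenzymes; promiscuous exporter gene)
        rxn("T_glc", {"glc_e": -1, "glc_c": 1}, 0, 1000, "g_hxt1 or g_hxt2"),
        rxn("T_gol", {"gol_e": -1, "gol_c": 1}, 0, 1000, "g_gut1"),
        rxn("T_meoh", {"meoh_e": -1, "meoh_c": 1}, 0, 1000),
        rxn("T_o2", {"o2_e": -1, "o2_c": 1}, 0, 1000),
        rxn("T_co2", {"co2_c": -1, "co2_e": 1}, 0, 1000),
        rxn("T_etoh", {"etoh_c": -1, "etoh_e": 1}, 0, 1000, "g_multi"),
        rxn("T_arab", {"arab_c": -1, "arab_e": 1}, 0, 1000, "g_multi"),
        rxn("T_hsod", {"hsod_c": -1, "hsod_e": 1}, 0, 1000, "g_sec1 or g_sec2"),
        # central carbon and redox
        rxn("R_glyco",
            {"glc_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
             "pyr_c": 2, "atp_c": 2, "nadh_c": 2, "h2o_c": 2},
            0, 1000, "g_glk1", name="glycolysis (lumped)"),
        rxn("R_golox", {"gol_c": -1, "nad_c": -1, "pyr_c": 1, "nadh_c": 1},
            0, 1000, "g_gut2", name="glycerol oxidation (lumped)"),
        rxn("R_aox",
            {"meoh_c": -1, "o2_c": -0.5, "nad_c": -1,
             "co2_c": 1, "nadh_c": 1, "h2o_c": 1},
            0, 1000, "g_aox1 or g_aox2", name="methanol oxidation"),
        rxn("R_resp",
            {"nadh_c": -1, "o2_c": -0.5, "adp_c": -2, "pi_c": -2,
             "nad_c": 1, "atp_c": 2, "h2o_c": 1},
            0, 1000, "g_cox1", name="respiratory chain (P/O = 2)"),
        rxn("R_ferm", {"pyr_c": -1, "nadh_c": -1, "etoh_c": 1, "co2_c": 1, "nad_c": 1},
            0, 1000, "g_adh1", name="ethanol fermentation"),
        # net NADH sink (arabitol is more reduced than pyruvate), so the
        # fermentative branch can balance redox when respiration is lost
        rxn("R_ard", {"pyr_c": -1, "nadh_c": -2, "arab_c": 1, "nad_c": 2},
            0, 0.05, "g_ard1", name="arabitol overflow (capacity-limited)"),
        rxn("R_tca",
            {"pyr_c": -1, "nad_c": -3, "adp_c": -1, "pi_c": -1, "h2o_c": -2,
             "co2_c": 3, "nadh_c": 3, "atp_c": 1},
            0, 1000, "g_pda1", name="pyruvate oxidation + TCA (lumped)"),
        # precursor biosynthesis (biomass monomers)
        rxn("R_gly_syn",
            {"pyr_c": -1, "atp_c": -1, "gly_c": 1, "adp_c": 1, "pi_c": 1, "co2_c": 1},
            0, 1000, "g_shm2", name="glycine synthesis"),
        rxn("R_ala_syn", {"pyr_c": -1, "nadh_c": -1, "ala_c": 1, "nad_c": 1},
            0, 1000, "g_alt1 or g_alt2", name="alanine synthesis (isoenzymes)"),
        rxn("R_carb_syn",
            {"pyr_c": -2, "atp_c": -2, "nadh_c": -2,
             "glucan_c": 1, "adp_c": 2, "pi_c": 2, "nad_c": 2},
            0, 1000, "g_psa1", name="structural carbohydrate synthesis"),
        rxn("R_glyg_syn",
            {"pyr_c": -2, "atp_c": -2, "nadh_c": -2,
             "glycogen_c": 1, "adp_c": 2, "pi_c": 2, "nad_c": 2},
            0, 1000, "g_gsy1", name="glycogen synthesis"),
        rxn("R_tre_syn",
            {"pyr_c": -4, "atp_c": -4, "nadh_c": -4,
             "trehalose_c": 1, "adp_c": 4, "pi_c": 4, "nad_c": 4},
            0, 1000, "g_tps1", name="trehalose synthesis"),
        rxn("R_lip_syn",
            {"pyr_c": -4, "atp_c": -4, "nadh_c": -6,
             "lipid_c": 1, "adp_c": 4, "pi_c": 4, "nad_c": 6, "co2_c": 2},
            0, 1000, "g_fas1 and g_fas2", name="lipid synthesis (FAS complex)"),
        rxn("R_nmp_syn",
            {"pyr_c": -2, "atp_c": -4, "nad_c": -1, "h2o_c": -1,
             "nmp_c": 1, "adp_c": 4, "pi_c": 4, "nadh_c": 1, "co2_c": 1},
            0, 1000, "g_ura2", name="ribonucleotide synthesis"),
        rxn("R_dnmp_syn",
            {"nmp_c": -1, "atp_c": -1, "nadh_c": -1,
             "dnmp_c": 1, "adp_c": 1, "pi_c": 1, "nad_c": 1},
            0, 1000, "g_rnr1", name="deoxyribonucleotide synthesis"),
        # non-growth-associated maintenance: free ATP dissipation, so the
        # forced substrate throughput stays balanceable in slow-growth mutants
        rxn("R_ngam", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
            0, 1000, name="ATP maintenance"),
        # heterologous product: amino-acid + ATP drain
        rxn("R_hsod",
            {"gly_c": -2, "ala_c": -2, "atp_c": -4,
             "hsod_c": 1, "adp_c": 4, "pi_c": 4},
            0, 1000, "g_hsod", name="heterologous protein synthesis"),
        rxn("DM_biomass", {"biomass_c": -1}, 0, 1000, exchange=True),
    ]

    model = MetabolicModel(
        model_id="bofsens_core_fixture",
        compartments=comp_c,
        metabolites=mets,
        reactions=reactions,
    )
    compositions = _core_compositions()
    register_compositions(
        model, compositions, monomer_table=CORE_MONOMER_TABLE,
        biomass_metabolite="biomass_c", energy=EnergyMetabolites(),
    )
    set_active_biomass(model, compositions[0].id)

    phenotypes = {
        g: ("inviable" if g in CORE_ESSENTIAL_GENES else "viable")
        for g in model.genes
    }
    return model, compositions, phenotypes


def core_constraints(condition: str = "glucose") -> ConstraintSet:
    """Measured-rate constraint sets for the core fixture.

    ``glucose``: the essentiality-screen convention (glucose uptake fixed
    to 1, everything else free).  ``oxygen_limited``: glucose and oxygen
    both fixed, creating an overflow regime for knockout ranking.
    ``met_gly``: glycerol/methanol co-feed in the style of a chemostat
    condition, used for the biomass scan.
    """
    if condition == "glucose":
        # glucose is the sole carbon source: its uptake is fixed to unity
        # and the alternative carbon exchanges are closed
        return ConstraintSet(
            uptake={"EX_glc": 1.0, "EX_gol": 0.0, "EX_meoh": 0.0},
            name="glucose",
        )
    if condition == "oxygen_limited":
        return ConstraintSet(
            uptake={"EX_glc": 1.0, "EX_o2": 1.0, "EX_gol": 0.0, "EX_meoh": 0.0},
            name="oxygen_limited",
        )
    if condition == "met_gly":
        return ConstraintSet(
            uptake={
                "EX_gol": 1.64, "EX_meoh": 0.81, "EX_o2": 3.09, "EX_glc": 0.0,
            },
            dilution_rate=0.1,
            name="met_gly",
        )
    raise KeyError(f"unknown fixture condition {condition!r}")


# ---------------------------------------------------------------------------
# random toy networks with constructed essentiality ground truth
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Parameters for :func:`generate_random_network`."""

    seed: int = 0
    n_linear_pathways: int = 2
    n_parallel_pathways: int = 1
    n_isoenzyme_pairs: int = 1
    max_chain_length: int = 2
    include_product_pathway: bool = False
    epsilon: float = 0.2  # biomass perturbation magnitude for generated sets

    def __post_init__(self) -> None:
        for name in ("n_linear_pathways", "n_parallel_pathways",
                     "n_isoenzyme_pairs", "max_chain_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.epsilon <= 0.5):
            raise ValueError("epsilon must be in [0, 0.5]")
        if (self.n_linear_pathways + self.n_parallel_pathways
                + self.n_isoenzyme_pairs) == 0:
            raise ValueError("network needs at least one pathway")


def generate_random_network(
    spec: FixtureSpec,
) -> Tuple[MetabolicModel, Set[str]]:
    """Random toy network with an exact essential-gene ground truth.

    Each *linear* pathway is the sole route from its own carbon source to
    an obligatory biomass precursor, so every gene on it is essential by
    construction.  *Parallel* pathways duplicate the final step as two
    separately catalysed reactions; *isoenzyme* pathways put an OR pair
    on a single reaction — in both motifs each individual gene is
    dispensable.  All generated networks are feasible (growth 1 with
    unit uptakes) and dead-end free.
    """
    rng = np.random.default_rng(spec.seed)
    mets: List[Metabolite] = []
    rxns: List[Reaction] = []
    essential: Set[str] = set()
    precursors: List[str] = []
    gene_counter = 0

    def new_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"g{gene_counter:03d}"

    def add_pathway(idx: int, motif: str) -> None:
        src_e = f"s{idx}_e"
        mets.append(Metabolite(src_e, compartment="e"))
        rxns.append(Reaction(
            id=f"EX_s{idx}", stoichiometry={src_e: -1},
            lower_bound=-1.0, upper_bound=1000.0, is_exchange=True,
        ))
        chain_len = int(rng.integers(1, spec.max_chain_length + 1))
        prev = src_e
        for step in range(chain_len):
            nxt = f"m{idx}_{step}_c"
            mets.append(Metabolite(nxt, compartment="c"))
            if motif == "linear":
                gene = new_gene()
                gpr = parse_gpr(gene)
                essential.add(gene)
            else:
                # redundant motifs carry genes only on the duplicated
                # final step, so their gene sets are fully dispensable
                gpr = parse_gpr("")
            rxns.append(Reaction(
                id=f"R{idx}_{step}", stoichiometry={prev: -1, nxt: 1},
                lower_bound=0.0, upper_bound=1000.0, gpr=gpr,
            ))
            prev = nxt
        prec = f"p{idx}_c"
        mets.append(Metabolite(prec, compartment="c"))
        precursors.append(prec)
        if motif == "linear":
            gene = new_gene()
            rxns.append(Reaction(
                id=f"R{idx}_final", stoichiometry={prev: -1, prec: 1},
                lower_bound=0.0, upper_bound=1000.0, gpr=parse_gpr(gene),
            ))
            essential.add(gene)
        elif motif == "parallel":
            for tag in ("a", "b"):
                rxns.append(Reaction(
                    id=f"R{idx}_final_{tag}", stoichiometry={prev: -1, prec: 1},
                    lower_bound=0.0, upper_bound=1000.0, gpr=parse_gpr(new_gene()),
                ))
        else:  # isoenzyme OR pair on a single reaction
            rule = f"{new_gene()} or {new_gene()}"
            rxns.append(Reaction(
                id=f"R{idx}_final", stoichiometry={prev: -1, prec: 1},
                lower_bound=0.0, upper_bound=1000.0, gpr=parse_gpr(rule),
            ))

    motifs = (
        ["linear"] * spec.n_linear_pathways
        + ["parallel"] * spec.n_parallel_pathways
        + ["iso"] * spec.n_isoenzyme_pairs
    )
    rng.shuffle(motifs)
    for idx, motif in enumerate(motifs):
        add_pathway(idx, motif)

    mets.append(Metabolite("biomass_c", compartment="c"))
    biomass_stoich = {p: -1.0 for p in precursors}
    biomass_stoich["biomass_c"] = 1.0
    rxns.append(Reaction(
        id="BIOMASS", stoichiometry=biomass_stoich,
        lower_bound=0.0, upper_bound=1000.0, is_biomass=True,
    ))
    rxns.append(Reaction(
        id="DM_biomass", stoichiometry={"biomass_c": -1},
        lower_bound=0.0, upper_bound=1000.0, is_exchange=True,
    ))
    if spec.include_product_pathway:
        mets.append(Metabolite("prod_c", compartment="c"))
        rxns.append(Reaction(
            id="R_product", stoichiometry={precursors[0]: -1, "prod_c": 1},
            lower_bound=0.0, upper_bound=1000.0, gpr=parse_gpr(new_gene()),
        ))
        rxns.append(Reaction(
            id="EX_product", stoichiometry={"prod_c": -1},
            lower_bound=0.0, upper_bound=1000.0, is_exchange=True,
        ))

    model = MetabolicModel(
        model_id=f"random_net_seed{spec.seed}",
        compartments=["e", "c"],
        metabolites=mets,
        reactions=rxns,
        objective_id="BIOMASS",
    )
    model.register_biomass("base", "BIOMASS")
    return model, essential


# ---------------------------------------------------------------------------
# perturbed biomass-composition sets
# ---------------------------------------------------------------------------

def generate_biomass_set(
    base: BiomassComposition,
    k: int,
    epsilon: float,
    seed: int = 0,
) -> List[BiomassComposition]:
    """k compositions with macro fractions and GAM perturbed by up to
    +/- epsilon (relative), renormalised to the base total mass.

    Monomer profiles are jittered and renormalised likewise, so every
    output passes the composition invariants.  epsilon = 0 reproduces the
    base exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 <= epsilon <= 0.5):
        raise ValueError("epsilon must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    base_total = base.total_mass
    out: List[BiomassComposition] = []
    for i in range(k):
        fracs = {}
        for pool, f in base.macro_fractions.items():
            fracs[pool] = f * (1.0 + rng.uniform(-epsilon, epsilon))
        scale = base_total / sum(fracs.values()) if sum(fracs.values()) else 1.0
        fracs = {p: f * scale for p, f in fracs.items()}
        gam = base.gam * (1.0 + rng.uniform(-epsilon, epsilon))

        def perturb_profile(profile: Dict[str, float]) -> Dict[str, float]:
            if not profile:
                return {}
            vals = {
                m: x * (1.0 + rng.uniform(-epsilon, epsilon))
                for m, x in profile.items()
            }
            total = sum(vals.values())
            return {m: v / total for m, v in vals.items()}

        out.append(BiomassComposition(
            id=f"{base.id}_perturbed_{i}",
            macro_fractions=fracs,
            gam=gam,
            protein_profile=perturb_profile(base.protein_profile),
            carb_profile=perturb_profile(base.carb_profile),
            lipid_profile=perturb_profile(base.lipid_profile),
            rna_profile=perturb_profile(base.rna_profile),
            dna_profile=perturb_profile(base.dna_profile),
            condition={"derived_from": base.id, "epsilon": epsilon, "index": i},
        ))
    return out
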