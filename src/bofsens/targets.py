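"""Strain-design target identification.

* **FSEOF** (flux scanning based on enforced objective flux): progressively
  forces product formation upward while maximising growth and keeps the
  reactions whose flux magnitude rises monotonically — overexpressing the
  enzymes of those reactions should pull flux toward the product.
  Reactions catalysed by isoenzymes (OR in the GPR) or promiscuous
  enzymes (gene shared by several reactions) are excluded from the gene
  candidate list; only 1:1 gene-reaction mappings qualify.

* **knockout ranking**: a variability-based score over 1:1-mapped genes.
  This is NOT a replication of any published knockout-design scoring
  scheme: each viable deletion is scored by the minimum product flux the
  mutant guarantees when its growth is pinned to a fraction of its
  maximum, which rewards deletions that force carbon toward the product.

* **robustness classification** across biomass compositions: a candidate
  found under every composition is *robust*; one found under only some
  is *conditional*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .lp import InfeasibleProblemError, apply_constraints, fba
from .model import ConstraintSet, MetabolicModel

__all__ = [
    "FseofResult",
    "fseof",
    "KnockoutRanking",
    "knockout_rank",
    "TargetRobustness",
    "classify_target_robustness",
]


def one_to_one_genes(model: MetabolicModel) -> Dict[str, str]:
    """Genes with a 1:1 gene-reaction mapping.

    A gene qualifies when it is the entire GPR of exactly one reaction
    (single leaf — no isoenzyme OR, no complex AND) and appears in no
    other reaction's rule.  Returns gene -> reaction id.
    """
    out: Dict[str, str] = {}
    for rxn in model.reactions.values():
        if rxn.gpr.kind == "gene":
            gene = rxn.gpr.gene
            if len(model.reactions_for_gene(gene)) == 1:
                out[gene] = rxn.id
    return out


@dataclass
class FseofResult:
    product_id: str
    enforced_levels: List[float]
    #: reaction id -> flux at baseline followed by each enforced level
    trajectories: Dict[str, List[float]]
    candidate_reactions: List[str]
    candidate_genes: List[str]
    #: reaction id -> reason it was excluded from the gene candidate list
    exclusion_log: Dict[str, str] = field(default_factory=dict)
    dropped_levels: List[float] = field(default_factory=list)

    def trajectory_frame(self) -> pd.DataFrame:
        idx = ["baseline"] + [f"level_{k}" for k in range(len(self.enforced_levels))]
        return pd.DataFrame(self.trajectories, index=idx).T


def _monotone_increase(traj: Sequence[float], tol: float) -> bool:
    """|flux| non-decreasing within tol, total rise > tol, no sign flip."""
    mags = [abs(v) for v in traj]
    for prev, cur in zip(mags, mags[1:]):
        if cur < prev - tol:
            return False
    if mags[-1] - mags[0] <= tol:
        return False
    signs = {1 if v > tol else -1 for v in traj if abs(v) > tol}
    return len(signs) <= 1


def fseof(
    model: MetabolicModel,
    constraints: Optional[ConstraintSet],
    product: str,
    steps: int = 10,
    max_fraction: float = 0.9,
    tol: float = 1e-6,
) -> FseofResult:
    """Scan for overexpression candidates by enforcing product formation.

    The product flux is raised as a lower bound in ``steps`` evenly
    spaced levels from its baseline (growth-optimal) value up to
    ``max_fraction`` of its theoretical maximum, maximising growth at
    each level.  Candidate reactions have monotonically increasing flux
    magnitude with no sign change; candidate genes come only from
    candidate reactions with a 1:1 gene-reaction mapping.
    """
    if product not in model.reactions:
        raise KeyError(f"product reaction {product!r} not in model")
    work = apply_constraints(model, constraints) if constraints else model.copy()

    base = fba(work)
    if not base.optimal:
        raise InfeasibleProblemError(f"baseline FBA is {base.status}")
    v_base = base.fluxes[product]
    vmax_sol = fba(work, objective=product, sense="max")
    if not vmax_sol.optimal or vmax_sol.objective_value <= tol:
        raise InfeasibleProblemError(
            f"product {product!r} not producible under these constraints"
        )
    v_top = max_fraction * vmax_sol.objective_value
    levels = list(np.linspace(v_base, v_top, steps + 1)[1:])

    rxn_ids = list(work.reactions)
    trajectories: Dict[str, List[float]] = {
        rid: [base.fluxes[rid]] for rid in rxn_ids
    }
    saved_bounds = work.reactions[product].bounds
    kept_levels: List[float] = []
    dropped: List[float] = []
    for level in levels:
        work.reactions[product].bounds = (
            level, max(saved_bounds[1], level)
        )
        sol = fba(work, objective=base.objective_id)
        if not sol.optimal:
            dropped.append(level)
            continue
        kept_levels.append(level)
        for rid in rxn_ids:
            trajectories[rid].append(sol.fluxes[rid])
    work.reactions[product].bounds = saved_bounds
    if not kept_levels:
        raise InfeasibleProblemError("every enforcement level was infeasible")

    candidates = [
        rid for rid in rxn_ids if _monotone_increase(trajectories[rid], tol)
    ]

    one2one = one_to_one_genes(work)
    rxn_to_gene = {rid: g for g, rid in one2one.items()}
    genes: List[str] = []
    exclusions: Dict[str, str] = {}
    for rid in candidates:
        gpr = work.reactions[rid].gpr
        if gpr.is_empty:
            exclusions[rid] = "no gene association"
        elif gpr.kind == "or" or any(c.kind == "or" for c in gpr.children):
            exclusions[rid] = "isoenzyme (OR rule)"
        elif gpr.kind != "gene":
            exclusions[rid] = "enzyme complex (AND rule), not 1:1"
        elif rid not in rxn_to_gene:
            exclusions[rid] = "promiscuous enzyme (gene shared across reactions)"
        else:
            genes.append(rxn_to_gene[rid])
    return FseofResult(
        product_id=product,
        enforced_levels=kept_levels,
        trajectories={rid: trajectories[rid] for rid in rxn_ids},
        candidate_reactions=sorted(candidates),
        candidate_genes=sorted(genes),
        exclusion_log=exclusions,
        dropped_levels=dropped,
    )


@dataclass
class KnockoutRanking:
    product_id: str
    #: (gene, score, mutant_growth) sorted best-first
    ranking: List[Tuple[str, float, float]]
    excluded: Dict[str, str] = field(default_factory=dict)

    def genes(self) -> List[str]:
        return [g for g, _, _ in self.ranking]

    def rank_of(self, gene: str) -> Optional[int]:
        for i, (g, _, _) in enumerate(self.ranking, start=1):
            if g == gene:
                return i
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"rank": i, "gene": g, "score": s, "mutant_growth": mu}
                for i, (g, s, mu) in enumerate(self.ranking, start=1)
            ]
        )


def knockout_rank(
    model: MetabolicModel,
    constraints: Optional[ConstraintSet],
    product: str,
    growth_floor: float = 0.5,
    score_tol: float = 1e-9,
) -> KnockoutRanking:
    """Rank 1:1-mapped gene deletions by guaranteed product flux.

    For each candidate gene: delete it; discard the mutant if its maximum
    growth drops below ``growth_floor`` of wild type (or is infeasible);
    otherwise pin growth to ``growth_floor`` of the mutant maximum and
    score the deletion by the FVA minimum of the product flux — the
    secretion the mutant cannot avoid.  Ties break by higher mutant
    growth, then lexicographic gene id, giving a deterministic total
    order.
    """
    if product not in model.reactions:
        raise KeyError(f"product reaction {product!r} not in model")
    work = apply_constraints(model, constraints) if constraints else model.copy()
    wt = fba(work)
    if not wt.optimal or wt.objective_value <= 0:
        raise InfeasibleProblemError("wild type does not grow; cannot rank knockouts")
    z_wt = wt.objective_value
    objective = work.objective_id

    candidates = one_to_one_genes(work)
    scored: List[Tuple[str, float, float]] = []
    excluded: Dict[str, str] = {}
    for gene, rid in sorted(candidates.items()):
        saved = work.reactions[rid].bounds
        work.reactions[rid].bounds = (0.0, 0.0)
        try:
            mutant = fba(work)
            if not mutant.optimal or mutant.objective_value < growth_floor * z_wt:
                excluded[gene] = "mutant growth below floor"
                continue
            z_mut = mutant.objective_value
            obj_rxn = work.reactions[objective]
            saved_obj = obj_rxn.bounds
            # growth is FIXED (equality) at the floor so that surplus
            # substrate cannot be absorbed by extra biomass formation
            obj_rxn.bounds = (growth_floor * z_mut, growth_floor * z_mut)
            try:
                vmin = fba(work, objective=product, sense="min")
                if not vmin.optimal:
                    excluded[gene] = "product minimisation infeasible"
                    continue
                score = vmin.objective_value
            finally:
                obj_rxn.bounds = saved_obj
            scored.append((gene, max(score, 0.0), z_mut))
        finally:
            work.reactions[rid].bounds = saved
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return KnockoutRanking(product_id=product, ranking=scored, excluded=excluded)


@dataclass
class TargetRobustness:
    robust: Set[str]
    conditional: Set[str]
    #: genes whose rank moves more than the allowed displacement
    rank_unstable: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    @property
    def all_candidates(self) -> Set[str]:
        return self.robust | self.conditional


def classify_target_robustness(
    per_composition: Mapping[str, Sequence[str] | KnockoutRanking],
    max_rank_displacement: int = 2,
) -> TargetRobustness:
    """Partition candidates into robust (all compositions) vs conditional.

    Accepts per-composition gene sets (FSEOF candidates) or rankings.
    For rankings, genes whose best and worst rank across compositions
    differ by more than ``max_rank_displacement`` are listed as
    rank-unstable.
    """
    if not per_composition:
        raise ValueError("no per-composition candidates given")
    gene_sets: Dict[str, Set[str]] = {}
    rank_maps: Dict[str, Dict[str, int]] = {}
    for comp_id, entry in per_composition.items():
        if isinstance(entry, KnockoutRanking):
            genes = entry.genes()
            rank_maps[comp_id] = {g: i for i, g in enumerate(genes, start=1)}
            gene_sets[comp_id] = set(genes)
        else:
            gene_sets[comp_id] = set(entry)
    robust = set.intersection(*gene_sets.values())
    union = set.union(*gene_sets.values())
    unstable: Dict[str, Tuple[int, int]] = {}
    if rank_maps:
        for gene in union:
            ranks = [rm[gene] for rm in rank_maps.values() if gene in rm]
            if len(ranks) >= 2 and max(ranks) - min(ranks) > max_rank_displacement:
                unstable[gene] = (min(ranks), max(ranks))
    return TargetRobustness(
        robust=robust, conditional=union - robust, rank_unstable=unstable
    )
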