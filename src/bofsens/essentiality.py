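"""Single-gene deletion phenotyping and confusion-matrix benchmarking.

A gene deletion disables every reaction whose GPR rule evaluates inactive
with that gene removed (AND = complex subunit lost; OR = isoenzyme
backup survives).  The mutant model is re-solved by FBA and the deletion
is called inviable when the mutant objective falls below a viability
threshold.  The conventional condition for essentiality screens fixes the
glucose uptake rate alone to unity and leaves other exchanges at their
defaults.

Predicted phenotypes are benchmarked against a reference (e.g. phenotypes
of orthologs in a well-characterised relative) with a standard confusion
matrix in which *viable* is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .lp import fba
from .model import ConstraintSet, MetabolicModel

__all__ = [
    "VIABILITY_THRESHOLD",
    "GeneDeletionOutcome",
    "EssentialityResult",
    "ConfusionMatrix",
    "single_gene_deletions",
    "confusion_matrix",
]

#: a mutant with absolute FBA objective below this is called inviable
VIABILITY_THRESHOLD = 1e-6

VIABLE = "viable"
INVIABLE = "inviable"


@dataclass
class GeneDeletionOutcome:
    gene: str
    phenotype: str  # viable | inviable
    growth_ratio: float  # mutant objective / wild-type objective
    mutant_objective: float
    disabled_reactions: List[str] = field(default_factory=list)


@dataclass
class EssentialityResult:
    outcomes: Dict[str, GeneDeletionOutcome]
    wild_type_objective: float

    def phenotypes(self) -> Dict[str, str]:
        return {g: o.phenotype for g, o in self.outcomes.items()}

    def essential_genes(self) -> List[str]:
        return sorted(g for g, o in self.outcomes.items() if o.phenotype == INVIABLE)

    @property
    def fraction_essential(self) -> float:
        if not self.outcomes:
            return 0.0
        return len(self.essential_genes()) / len(self.outcomes)


def single_gene_deletions(
    model: MetabolicModel,
    constraints: Optional[ConstraintSet] = None,
    threshold: float = VIABILITY_THRESHOLD,
    genes: Optional[List[str]] = None,
) -> EssentialityResult:
    """Phenotype every gene (or the given subset) by single deletion.

    For each gene, reactions whose GPR evaluates inactive under the
    deletion get bounds (0, 0); FBA is re-run; the phenotype is inviable
    iff the mutant objective is below ``threshold`` (absolute).  The
    working model is restored after every deletion, and the caller's
    model is never modified (all work happens on a copy).
    """
    work = model.copy()
    if constraints is not None:
        constraints.validate_against(work)
        for rxn_id, bnds in constraints.bounds_map().items():
            work.reactions[rxn_id].bounds = bnds
    wild_type = fba(work)
    if not wild_type.optimal:
        raise RuntimeError(
            f"wild-type FBA is {wild_type.status}; cannot phenotype deletions"
        )
    z0 = wild_type.objective_value
    if z0 <= 0:
        raise RuntimeError("wild-type objective is zero; cannot phenotype deletions")

    gene_list = genes if genes is not None else work.genes
    outcomes: Dict[str, GeneDeletionOutcome] = {}
    for gene in gene_list:
        affected = [
            rid
            for rid in work.reactions_for_gene(gene)
            if not work.reactions[rid].gpr.is_active({gene})
        ]
        if not affected:
            outcomes[gene] = GeneDeletionOutcome(
                gene=gene, phenotype=VIABLE, growth_ratio=1.0, mutant_objective=z0
            )
            continue
        saved = {rid: work.reactions[rid].bounds for rid in affected}
        for rid in affected:
            work.reactions[rid].bounds = (0.0, 0.0)
        mutant = fba(work)
        for rid, bnds in saved.items():
            work.reactions[rid].bounds = bnds
        z = mutant.objective_value if mutant.optimal else 0.0
        ratio = min(max(z / z0, 0.0), 1.0 + 1e-6)
        outcomes[gene] = GeneDeletionOutcome(
            gene=gene,
            phenotype=INVIABLE if z < threshold else VIABLE,
            growth_ratio=ratio,
            mutant_objective=z,
            disabled_reactions=affected,
        )
    return EssentialityResult(outcomes=outcomes, wild_type_objective=z0)


@dataclass
class ConfusionMatrix:
    """Viable-as-positive confusion matrix with derived percentage metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    excluded_genes: List[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fn)

    @property
    def percent_correct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total

    def metrics(self, digits: int = 1) -> Dict[str, float]:
        """Metrics in percent, rounded to ``digits`` decimal places."""
        return {
            "sensitivity": round(self.sensitivity, digits),
            "specificity": round(self.specificity, digits),
            "ppv": round(self.ppv, digits),
            "npv": round(self.npv, digits),
            "percent_correct": round(self.percent_correct, digits),
        }

    def metrics_rounded(self) -> Dict[str, int]:
        """Metrics rounded to the nearest whole percent."""
        return {k: int(round(v)) for k, v in self.metrics(digits=6).items()}


def confusion_matrix(
    predictions: EssentialityResult | Dict[str, str],
    reference: Dict[str, str],
) -> ConfusionMatrix:
    """Benchmark predicted phenotypes against reference phenotypes.

    Viable is the positive class: TP = both viable, TN = both inviable,
    FP = predicted viable but reference inviable, FN = the converse.
    Genes without a reference phenotype are excluded from the counts and
    listed in ``excluded_genes``.
    """
    if isinstance(predictions, EssentialityResult):
        predictions = predictions.phenotypes()
    overlap = [g for g in predictions if g in reference]
    if not overlap:
        raise ValueError("no overlap between predicted and reference gene sets")
    tp = fp = tn = fn = 0
    for gene in overlap:
        pred_viable = predictions[gene] == VIABLE
        ref_viable = reference[gene] == VIABLE
        if pred_viable and ref_viable:
            tp += 1
        elif pred_viable and not ref_viable:
            fp += 1
        elif not pred_viable and not ref_viable:
            tn += 1
        else:
            fn += 1
    excluded = sorted(set(predictions) - set(reference))
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn, excluded_genes=excluded)
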