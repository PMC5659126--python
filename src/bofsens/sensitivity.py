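"""Biomass-composition sensitivity analyses.

Three analyses quantify how the choice of biomass equation propagates
into model predictions:

* a **composition scan** re-runs FBA under each registered biomass
  equation and records predicted growth rate and CO2 exchange rate (CER)
  with percent errors against measured values;

* a **flux-significance procedure** draws, for each condition, n
  independent uniform samples per reaction from its FVA allowable range,
  then flags a reaction as significantly changed between two conditions
  when a two-sided Mann-Whitney U test gives p < alpha AND the fold
  change of the mean sampled fluxes exceeds a threshold (defaults
  alpha = 0.01, FC > 2, n = 100; flux magnitudes below 1e-5 are taken
  as zero);

* **correlation matrices** (Pearson) over per-condition flux vectors and
  over biomass coefficient vectors.

Note the sampled vectors are independent per reaction and therefore not
stoichiometrically consistent; the procedure probes the geometry of the
FVA envelope, not a feasible flux sample.  This is deliberate and
documented in the methods note.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .biomass import BiomassComposition
from .lp import ZERO_FLUX_TOL, FluxRange, apply_constraints, fba, fva
from .model import ConstraintSet, MetabolicModel, set_active_biomass

__all__ = [
    "SignificanceRecord",
    "ScanReport",
    "sample_flux_distribution",
    "mann_whitney_u",
    "pairwise_significance",
    "correlation_matrix",
    "biomass_scan",
    "condition_flux_ranges",
    "significance_scan",
    "sample_size_stability",
]

DEFAULT_ALPHA = 0.01
DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_SAMPLE_SIZE = 100
#: largest min(n, m) for which the exact U distribution is used
EXACT_U_LIMIT = 8


# ---------------------------------------------------------------------------
# sampling within FVA ranges
# ---------------------------------------------------------------------------

def _stream(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-label RNG stream.

    Streams are derived by stable hashing of the labels so results are
    invariant to reaction iteration order and reproducible across runs.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(lab.encode()) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def sample_flux_distribution(
    ranges: FluxRange,
    n: int = DEFAULT_SAMPLE_SIZE,
    seed: int = 0,
    label: str = "",
) -> Dict[str, np.ndarray]:
    """Draw n independent uniform values per reaction within its range.

    Degenerate ranges yield n copies of the single value.  ``label``
    (typically the condition/composition id) separates the random streams
    of different conditions sampled under the same seed.
    """
    if n < 2:
        raise ValueError(f"sample size must be >= 2, got {n}")
    out: Dict[str, np.ndarray] = {}
    for rid, (lo, hi) in ranges.ranges.items():
        if hi - lo <= 0.0:
            out[rid] = np.full(n, lo)
        else:
            rng = _stream(seed, label, rid)
            out[rid] = rng.uniform(lo, hi, size=n)
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney / fold-change significance
# ---------------------------------------------------------------------------

def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Uses the exact null distribution for small untied samples
    (min(n, m) <= 8), otherwise the normal approximation with continuity
    and tie correction.  Two samples with zero combined variance (all
    values identical) give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = min(len(x), len(y)) <= EXACT_U_LIMIT
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if math.isnan(p):  # fully tied ranks under the asymptotic path
        return 1.0
    return min(p, 1.0)


@dataclass
class SignificanceRecord:
    """Per-reaction outcome of one pairwise condition comparison."""

    reaction_id: str
    pair: Tuple[str, str]
    p_value: float
    fold_change: float
    mean_i: float
    mean_j: float
    significant: bool


def _zeroed_mean(values: np.ndarray, zero_tol: float) -> float:
    vals = np.where(np.abs(values) < zero_tol, 0.0, values)
    m = float(np.mean(vals))
    return 0.0 if abs(m) < zero_tol else m


def fold_change(mean_i: float, mean_j: float) -> float:
    """Ratio of the larger to the smaller absolute mean flux.

    Both zero -> 1 (no change); exactly one zero -> +inf (appearance or
    disappearance of flux); always >= 1 by construction.
    """
    a, b = abs(mean_i), abs(mean_j)
    if a == 0.0 and b == 0.0:
        return 1.0
    if a == 0.0 or b == 0.0:
        return math.inf
    return max(a, b) / min(a, b)


def pairwise_significance(
    samples_i: Mapping[str, np.ndarray],
    samples_j: Mapping[str, np.ndarray],
    pair: Tuple[str, str] = ("i", "j"),
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    zero_tol: float = ZERO_FLUX_TOL,
) -> List[SignificanceRecord]:
    """Flag reactions whose sampled flux differs between two conditions.

    Significant iff the Mann-Whitney p-value is below ``alpha`` and the
    fold change of mean sampled fluxes (computed after zeroing magnitudes
    below ``zero_tol``) exceeds ``fc_threshold``.
    """
    if set(samples_i) != set(samples_j):
        raise ValueError("conditions sample different reaction sets")
    records: List[SignificanceRecord] = []
    for rid in samples_i:
        xi, xj = samples_i[rid], samples_j[rid]
        if len(xi) != len(xj):
            raise ValueError(f"reaction {rid!r}: mismatched sample sizes")
        p = mann_whitney_u(xi, xj)
        mi = _zeroed_mean(np.asarray(xi, dtype=float), zero_tol)
        mj = _zeroed_mean(np.asarray(xj, dtype=float), zero_tol)
        fc = fold_change(mi, mj)
        records.append(
            SignificanceRecord(
                reaction_id=rid,
                pair=pair,
                p_value=p,
                fold_change=fc,
                mean_i=mi,
                mean_j=mj,
                significant=(p < alpha and fc > fc_threshold),
            )
        )
    return records


def records_to_frame(records: Iterable[SignificanceRecord]) -> pd.DataFrame:
    """Significance records as a tidy table with volcano-plot columns."""
    rows = []
    for r in records:
        log2fc = math.log2(r.fold_change) if math.isfinite(r.fold_change) else math.inf
        log10p = -math.log10(r.p_value) if r.p_value > 0 else math.inf
        rows.append(
            {
                "reaction_id": r.reaction_id,
                "condition_i": r.pair[0],
                "condition_j": r.pair[1],
                "p_value": r.p_value,
                "fold_change": r.fold_change,
                "mean_i": r.mean_i,
                "mean_j": r.mean_j,
                "log2_fc": log2fc,
                "neg_log10_p": log10p,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------

def correlation_matrix(vectors: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pearson correlation between equal-length condition vectors.

    Zero-variance vectors give missing (NaN) correlations rather than 0;
    the diagonal is 1 for every condition.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two conditions")
    ids = list(vectors)
    lengths = {len(vectors[c]) for c in ids}
    if len(lengths) != 1:
        raise ValueError("condition vectors have unequal lengths")
    arr = np.asarray([vectors[c] for c in ids], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr = np.atleast_2d(corr)
    sd = arr.std(axis=1)
    corr[sd == 0.0, :] = np.nan
    corr[:, sd == 0.0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# composition scan
# ---------------------------------------------------------------------------

@dataclass
class ScanReport:
    """Growth/CER predictions per biomass composition plus correlations."""

    predictions: pd.DataFrame
    flux_correlation: Optional[pd.DataFrame] = None
    coefficient_correlation: Optional[pd.DataFrame] = None
    infeasible: List[str] = field(default_factory=list)


def biomass_scan(
    model: MetabolicModel,
    compositions: Sequence[BiomassComposition],
    constraints: ConstraintSet,
    co2_exchange: str,
    experimental: Optional[Mapping[str, float]] = None,
    with_correlations: bool = True,
) -> ScanReport:
    """Repeat growth/CER prediction under each biomass composition.

    For each composition (already registered on the model) the matching
    biomass reaction is activated, FBA run under ``constraints``, and the
    predicted growth rate (objective) and CER (flux of ``co2_exchange``)
    recorded, with percent errors against ``experimental`` values
    (``{"growth": ..., "cer": ...}``) when given.  Infeasible
    compositions are flagged and the scan continues.
    """
    work = apply_constraints(model, constraints)
    rows = []
    infeasible: List[str] = []
    flux_vectors: Dict[str, np.ndarray] = {}
    rxn_order = list(work.reactions)
    coeff_vectors: Dict[str, np.ndarray] = {}
    met_order = list(work.metabolites)

    for comp in compositions:
        set_active_biomass(work, comp.id)
        sol = fba(work)
        row: Dict[str, object] = {"composition": comp.id}
        if not sol.optimal:
            infeasible.append(comp.id)
            row.update(growth=np.nan, cer=np.nan, status=sol.status)
        else:
            growth = sol.objective_value
            cer = sol.fluxes[co2_exchange]
            row.update(growth=growth, cer=cer, status="optimal")
            if experimental:
                if experimental.get("growth"):
                    row["growth_pct_error"] = (
                        abs(growth - experimental["growth"])
                        / experimental["growth"] * 100.0
                    )
                if experimental.get("cer"):
                    row["cer_pct_error"] = (
                        abs(cer - experimental["cer"]) / experimental["cer"] * 100.0
                    )
            flux_vectors[comp.id] = np.array(
                [sol.fluxes[r] for r in rxn_order]
            )
        biomass_rxn = work.reactions[work.biomass_registry[comp.id]]
        coeff_vectors[comp.id] = np.array(
            [biomass_rxn.stoichiometry.get(m, 0.0) for m in met_order]
        )
        rows.append(row)

    flux_corr = coeff_corr = None
    if with_correlations and len(flux_vectors) >= 2:
        flux_corr = correlation_matrix(flux_vectors)
        coeff_corr = correlation_matrix(
            {c: coeff_vectors[c] for c in flux_vectors}
        )
    return ScanReport(
        predictions=pd.DataFrame(rows),
        flux_correlation=flux_corr,
        coefficient_correlation=coeff_corr,
        infeasible=infeasible,
    )


# ---------------------------------------------------------------------------
# full significance pipeline across compositions
# ---------------------------------------------------------------------------

def condition_flux_ranges(
    model: MetabolicModel,
    compositions: Sequence[BiomassComposition],
    constraints: ConstraintSet,
    gamma: float = 1.0,
) -> Dict[str, FluxRange]:
    """FVA allowable ranges per composition at objective fraction gamma.

    The registered biomass reactions themselves are dropped from the
    ranges: each is active in exactly one condition and clamped to zero
    in the others, so a cross-condition comparison of their fluxes is
    meaningless (it would only restate which biomass equation defines
    each condition).
    """
    work = apply_constraints(model, constraints)
    biomass_rxns = set(work.biomass_registry.values())
    shared = [r for r in work.reactions if r not in biomass_rxns]
    ranges: Dict[str, FluxRange] = {}
    for comp in compositions:
        set_active_biomass(work, comp.id)
        ranges[comp.id] = fva(work, gamma=gamma, reactions=shared)
    return ranges


@dataclass
class SignificanceScan:
    records: List[SignificanceRecord]
    sample_size: int
    seed: int

    def significant_reactions(self, pair: Optional[Tuple[str, str]] = None) -> set:
        out = set()
        for r in self.records:
            if r.significant and (pair is None or set(r.pair) == set(pair)):
                out.add(r.reaction_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def significance_scan(
    ranges: Mapping[str, FluxRange],
    n: int = DEFAULT_SAMPLE_SIZE,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    zero_tol: float = ZERO_FLUX_TOL,
) -> SignificanceScan:
    """Run the sampling significance procedure over all condition pairs."""
    samples = {
        cid: sample_flux_distribution(rng, n=n, seed=seed, label=cid)
        for cid, rng in ranges.items()
    }
    records: List[SignificanceRecord] = []
    for ci, cj in combinations(sorted(ranges), 2):
        records.extend(
            pairwise_significance(
                samples[ci], samples[cj], pair=(ci, cj),
                alpha=alpha, fc_threshold=fc_threshold, zero_tol=zero_tol,
            )
        )
    return SignificanceScan(records=records, sample_size=n, seed=seed)


@dataclass
class StabilityReport:
    """How the significant sets vary with sample size."""

    reaction_sets: Dict[int, set]
    gene_sets: Dict[int, set]
    reaction_overlap_pct: float
    gene_overlap_pct: float
    pairwise_reaction_overlap: pd.DataFrame

    def counts(self) -> Dict[int, int]:
        return {n: len(s) for n, s in self.reaction_sets.items()}


def _overall_overlap(sets: Dict[int, set]) -> float:
    union = set().union(*sets.values())
    if not union:
        return 100.0
    inter = set.intersection(*sets.values())
    return 100.0 * len(inter) / len(union)


def sample_size_stability(
    ranges: Mapping[str, FluxRange],
    model: Optional[MetabolicModel] = None,
    sizes: Sequence[int] = (50, 100, 1000, 10000),
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    zero_tol: float = ZERO_FLUX_TOL,
) -> StabilityReport:
    """Repeat the significance procedure at several sample sizes.

    Reports the significant reaction set (union over all condition
    pairs) and, when a model is given, the associated gene set, at each
    size, together with pairwise and overall intersection-over-union
    percentages.
    """
    reaction_sets: Dict[int, set] = {}
    gene_sets: Dict[int, set] = {}
    for n in sizes:
        scan = significance_scan(
            ranges, n=n, seed=seed, alpha=alpha,
            fc_threshold=fc_threshold, zero_tol=zero_tol,
        )
        sig = scan.significant_reactions()
        reaction_sets[n] = sig
        genes: set = set()
        if model is not None:
            for rid in sig:
                genes |= model.reactions[rid].gpr.genes()
        gene_sets[n] = genes

    size_list = list(sizes)
    mat = np.zeros((len(size_list), len(size_list)))
    for a, na in enumerate(size_list):
        for b, nb in enumerate(size_list):
            union = reaction_sets[na] | reaction_sets[nb]
            inter = reaction_sets[na] & reaction_sets[nb]
            mat[a, b] = 100.0 * len(inter) / len(union) if union else 100.0
    return StabilityReport(
        reaction_sets=reaction_sets,
        gene_sets=gene_sets,
        reaction_overlap_pct=_overall_overlap(reaction_sets),
        gene_overlap_pct=_overall_overlap(gene_sets)
        if model is not None else 100.0,
        pairwise_reaction_overlap=pd.DataFrame(
            mat, index=size_list, columns=size_list
        ),
    )
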