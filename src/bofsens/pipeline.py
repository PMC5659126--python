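"""End-to-end pipeline orchestration and run configuration.

A :class:`RunConfig` collects every knob of the analysis chain
(load -> validate -> constrain -> biomass scan -> essentiality ->
flux-significance -> targets) and the pipeline writes each stage's
tables plus a machine-readable summary JSON.  All outputs carry the
seed and a config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import io_sbml, io_tabular
from .biomass import BiomassComposition
from .essentiality import confusion_matrix, single_gene_deletions
from .model import ConstraintSet, MetabolicModel, set_active_biomass, validate_model
from .sensitivity import (
    biomass_scan,
    condition_flux_ranges,
    sample_size_stability,
    significance_scan,
)
from .targets import classify_target_robustness, fseof, knockout_rank

__all__ = ["RunConfig", "run_pipeline", "load_model", "PipelineError"]

log = logging.getLogger("bofsens")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def load_model(path: str | Path, dialect: str = "auto") -> MetabolicModel:
    """Load a model in any supported dialect.

    ``dialect``: ``sbml-fbc``, ``sbml-cobra``, ``tabular``, or ``auto``
    (by file extension: .xml/.sbml -> SBML, anything else -> tabular).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = (
            "sbml" if path.suffix.lower() in (".xml", ".sbml") else "tabular"
        )
    if dialect in ("sbml", "sbml-fbc", "sbml-cobra"):
        sub = "auto" if dialect == "sbml" else dialect
        return io_sbml.read_sbml(path, dialect=sub)
    if dialect == "tabular":
        return io_tabular.read_tabular(path)
    raise ValueError(f"unknown model dialect {dialect!r}")


@dataclass
class RunConfig:
    """Configuration of a full analysis run (YAML round-trippable)."""

    model_path: str = ""
    model_dialect: str = "auto"
    output_dir: str = "bofsens_out"
    # constraint set (uptake/secretion magnitudes, mmol/gCDW/hr)
    uptake: Dict[str, float] = field(default_factory=dict)
    secretion: Dict[str, float] = field(default_factory=dict)
    # analysis parameters
    alpha: float = 0.01
    fc_threshold: float = 2.0
    zero_tol: float = 1e-5
    gamma: float = 1.0
    sample_sizes: List[int] = field(default_factory=lambda: [50, 100, 1000, 10000])
    significance_sample_size: int = 100
    seed: int = 0
    viability_threshold: float = 1e-6
    fseof_steps: int = 10
    fseof_max_fraction: float = 0.9
    knockout_growth_floor: float = 0.5
    # optional inputs
    co2_exchange: str = "EX_co2"
    product_reaction: Optional[str] = None
    reference_phenotypes_path: Optional[str] = None
    experimental_growth: Optional[float] = None
    experimental_cer: Optional[float] = None
    compositions: Optional[List[str]] = None  # subset of registry ids

    def __post_init__(self) -> None:
        for name in ("alpha", "fc_threshold", "zero_tol", "gamma",
                     "viability_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        """Hash of the scientifically meaningful parameters (the output
        location does not influence any result)."""
        payload = asdict(self)
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def constraint_set(self) -> ConstraintSet:
        return ConstraintSet(uptake=dict(self.uptake),
                             secretion=dict(self.secretion))


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config: {config.digest()}  seed: {config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(
    config: RunConfig,
    model: Optional[MetabolicModel] = None,
    compositions: Optional[Sequence[BiomassComposition]] = None,
) -> Dict[str, object]:
    """Execute the full analysis chain and write all outputs.

    ``model`` and ``compositions`` may be passed directly (e.g. the
    synthetic fixture); otherwise the model is loaded from
    ``config.model_path``.  Returns the summary dict (also written as
    ``summary.json``).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, object] = {
        "config_hash": config.digest(), "seed": config.seed, "stages": {},
    }
    stages: Dict[str, object] = summary["stages"]  # type: ignore[assignment]

    def stage(name: str):
        log.info("stage %s", name)
        t0 = time.perf_counter()

        def done(payload: object) -> None:
            stages[name] = {
                "elapsed_s": round(time.perf_counter() - t0, 3),
                "result": payload,
            }

        return done

    # -- load ---------------------------------------------------------
    done = stage("load")
    try:
        if model is None:
            model = load_model(config.model_path, config.model_dialect)
        else:
            model = model.copy()  # never mutate the caller's model
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    done({"reactions": len(model.reactions),
          "metabolites": len(model.metabolites),
          "genes": len(model.genes)})

    comp_ids = config.compositions or sorted(model.biomass_registry)
    unknown = [c for c in comp_ids if c not in model.biomass_registry]
    if unknown:
        raise PipelineError("load", f"unknown composition ids {unknown}")
    if compositions is not None:
        comp_map = {c.id: c for c in compositions}
        comps = [comp_map[c] for c in comp_ids if c in comp_map]
    else:
        comps = None

    # -- validate -----------------------------------------------------
    done = stage("validate")
    report = validate_model(model)
    done({"dead_ends": report.dead_end_metabolites,
          "blocked": len(report.blocked_reactions),
          "unreferenced_genes": report.unreferenced_genes})

    constraints = config.constraint_set()

    # -- biomass scan -------------------------------------------------
    done = stage("biomass_scan")
    experimental = {}
    if config.experimental_growth:
        experimental["growth"] = config.experimental_growth
    if config.experimental_cer:
        experimental["cer"] = config.experimental_cer
    if comps is not None:
        scan = biomass_scan(
            model, comps, constraints, co2_exchange=config.co2_exchange,
            experimental=experimental or None,
        )
        _write_table(scan.predictions, out_dir / "biomass_scan.tsv", config)
        if scan.flux_correlation is not None:
            scan.flux_correlation.to_csv(
                out_dir / "flux_correlation.tsv", sep="\t")
            scan.coefficient_correlation.to_csv(
                out_dir / "coefficient_correlation.tsv", sep="\t")
        done({"n_compositions": len(comps), "infeasible": scan.infeasible})
    else:
        done({"skipped": "no composition objects supplied"})

    # -- essentiality -------------------------------------------------
    done = stage("essentiality")
    set_active_biomass(model, comp_ids[0])
    ess = single_gene_deletions(
        model, constraints, threshold=config.viability_threshold)
    ess_df = pd.DataFrame([
        {"gene": g, "growth_ratio": o.growth_ratio, "phenotype": o.phenotype}
        for g, o in sorted(ess.outcomes.items())
    ])
    _write_table(ess_df, out_dir / "essentiality.tsv", config)
    payload: Dict[str, object] = {
        "n_genes": len(ess.outcomes),
        "fraction_essential": round(ess.fraction_essential, 4),
    }
    if config.reference_phenotypes_path:
        ref = pd.read_csv(
            config.reference_phenotypes_path, sep="\t",
            names=["gene", "phenotype"], comment="#", header=0,
        )
        cm = confusion_matrix(ess, dict(zip(ref.gene, ref.phenotype)))
        payload["confusion"] = {
            "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
            **cm.metrics(),
        }
        (out_dir / "essentiality_metrics.json").write_text(
            json.dumps(payload["confusion"], indent=2))
    done(payload)

    # -- significance -------------------------------------------------
    done = stage("significance")
    if comps is not None and len(comps) >= 2:
        ranges = condition_flux_ranges(
            model, comps, constraints, gamma=config.gamma)
        scan = significance_scan(
            ranges, n=config.significance_sample_size, seed=config.seed,
            alpha=config.alpha, fc_threshold=config.fc_threshold,
            zero_tol=config.zero_tol,
        )
        sig_df = scan.to_frame()
        _write_table(sig_df, out_dir / "significance.tsv", config)
        _write_table(
            sig_df[["reaction_id", "condition_i", "condition_j",
                    "log2_fc", "neg_log10_p", "significant"]],
            out_dir / "volcano.tsv", config,
        )
        stability = sample_size_stability(
            ranges, model=model, sizes=config.sample_sizes, seed=config.seed,
            alpha=config.alpha, fc_threshold=config.fc_threshold,
            zero_tol=config.zero_tol,
        )
        done({
            "significant_reactions": sorted(scan.significant_reactions()),
            "counts_by_size": {
                str(n): len(s) for n, s in stability.reaction_sets.items()},
            "reaction_overlap_pct": round(stability.reaction_overlap_pct, 2),
            "gene_overlap_pct": round(stability.gene_overlap_pct, 2),
        })
    else:
        done({"skipped": "needs >= 2 compositions"})

    # -- targets ------------------------------------------------------
    done = stage("targets")
    if config.product_reaction and comps is not None:
        fseof_sets: Dict[str, List[str]] = {}
        ko_rankings = {}
        for comp in comps:
            set_active_biomass(model, comp.id)
            res = fseof(
                model, constraints, config.product_reaction,
                steps=config.fseof_steps,
                max_fraction=config.fseof_max_fraction,
            )
            fseof_sets[comp.id] = res.candidate_genes
            ko_rankings[comp.id] = knockout_rank(
                model, constraints, config.product_reaction,
                growth_floor=config.knockout_growth_floor,
            )
        over = classify_target_robustness(fseof_sets)
        ko = classify_target_robustness(ko_rankings)
        rows = [
            {"gene": g, "analysis": "overexpression",
             "class": "robust" if g in over.robust else "conditional"}
            for g in sorted(over.all_candidates)
        ] + [
            {"gene": g, "analysis": "knockout",
             "class": "robust" if g in ko.robust else "conditional"}
            for g in sorted(ko.all_candidates)
        ]
        _write_table(pd.DataFrame(rows), out_dir / "targets.tsv", config)
        done({
            "overexpression": {
                "total": len(over.all_candidates),
                "robust": sorted(over.robust),
                "conditional": sorted(over.conditional)},
            "knockout": {
                "total": len(ko.all_candidates),
                "robust": sorted(ko.robust),
                "conditional": sorted(ko.conditional)},
        })
    else:
        done({"skipped": "no product reaction configured"})

    set_active_biomass(model, comp_ids[0])
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
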