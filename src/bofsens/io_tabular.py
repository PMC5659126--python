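"""Plain-text tabular model dialect.

One reaction per row in a TSV with columns ``id``, ``name``,
``equation``, ``lb``, ``ub``, ``gpr``, ``flags``.  Equations use
``"a[c] + 2 b[c] -> c[e]"`` syntax: metabolite id followed by its
compartment in square brackets, ``->`` separating substrates from
products (write ``<->`` for readability of reversible reactions; actual
reversibility is governed by the bounds).  ``flags`` is a comma-separated
set drawn from ``exchange``, ``biomass``, ``objective`` and
``biomass:<composition_id>`` registry entries.  Lines starting with ``#``
are comments; a ``# model: <id>`` comment carries the model id.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Tuple

from .gpr import parse_gpr
from .model import (
    DEFAULT_LOWER_BOUND,
    DEFAULT_UPPER_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = ["read_tabular", "write_tabular", "TabularFormatError"]

COLUMNS = ["id", "name", "equation", "lb", "ub", "gpr", "flags"]

_MET_RE = re.compile(r"^(?P<id>.+?)(?:\[(?P<comp>[^\]]+)\])?$")
_TERM_RE = re.compile(r"^(?:(?P<coeff>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(?P<met>\S+)$")


class TabularFormatError(ValueError):
    """Raised on malformed tabular model input, with line context."""


def _parse_side(text: str, line_no: int) -> List[Tuple[str, str, float]]:
    """Parse one side of an equation into (met id, compartment, coeff)."""
    out = []
    text = text.strip()
    if not text:
        return out
    for term in text.split(" + "):
        term = term.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise TabularFormatError(f"line {line_no}: cannot parse term {term!r}")
        coeff = float(m.group("coeff")) if m.group("coeff") else 1.0
        met_tok = m.group("met")
        mm = _MET_RE.match(met_tok)
        met_id, comp = mm.group("id"), mm.group("comp") or "c"
        out.append((met_id, comp, coeff))
    return out


def parse_equation(
    equation: str, line_no: int = 0
) -> Tuple[Dict[str, float], Dict[str, str]]:
    """Equation string -> (stoichiometry, metabolite compartments)."""
    for arrow in ("<->", "<=>", "->", "=>"):
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            break
    else:
        raise TabularFormatError(
            f"line {line_no}: equation {equation!r} lacks an arrow"
        )
    stoich: Dict[str, float] = {}
    comps: Dict[str, str] = {}
    for met_id, comp, coeff in _parse_side(left, line_no):
        stoich[met_id] = stoich.get(met_id, 0.0) - coeff
        comps[met_id] = comp
    for met_id, comp, coeff in _parse_side(right, line_no):
        stoich[met_id] = stoich.get(met_id, 0.0) + coeff
        comps[met_id] = comp
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise TabularFormatError(
            f"line {line_no}: equation {equation!r} has empty net stoichiometry"
        )
    return stoich, comps


def format_equation(rxn: Reaction, model: MetabolicModel) -> str:
    def side(items, sign):
        parts = []
        for met_id, coeff in items:
            c = abs(coeff)
            comp = model.metabolites[met_id].compartment
            tok = f"{met_id}[{comp}]"
            parts.append(tok if c == 1 else f"{c:.17g} {tok}")
        return " + ".join(parts)

    subs = [(m, c) for m, c in rxn.stoichiometry.items() if c < 0]
    prods = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<->" if rxn.reversible else "->"
    return f"{side(subs, -1)} {arrow} {side(prods, 1)}".strip()


def read_tabular(path: str | Path) -> MetabolicModel:
    path = Path(path)
    model_id = path.stem
    rows = []
    registry: Dict[str, str] = {}
    objective = None
    with open(path) as fh:
        header: List[str] | None = None
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*model:\s*(\S+)", line)
                if m:
                    model_id = m.group(1)
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in ("id", "equation") if c not in header]
                if missing:
                    raise TabularFormatError(
                        f"line {line_no}: header missing columns {missing}"
                    )
                continue
            row = dict(zip(header, fields))
            rows.append((line_no, row))

    if header is None:
        raise TabularFormatError(f"{path}: no header row found")

    metabolites: Dict[str, Metabolite] = {}
    reactions: List[Reaction] = []
    for line_no, row in rows:
        stoich, comps = parse_equation(row["equation"], line_no)
        for met_id, comp in comps.items():
            if met_id not in metabolites:
                metabolites[met_id] = Metabolite(met_id, compartment=comp)
            elif metabolites[met_id].compartment != comp:
                raise TabularFormatError(
                    f"line {line_no}: metabolite {met_id!r} re-declared in "
                    f"compartment {comp!r}"
                )
        flags = {
            f.strip() for f in row.get("flags", "").split(",") if f.strip()
        }
        is_exchange = "exchange" in flags
        is_biomass = "biomass" in flags
        for flag in flags:
            if flag.startswith("biomass:"):
                registry[flag.split(":", 1)[1]] = row["id"]
                is_biomass = True
        if "objective" in flags:
            objective = row["id"]
        lb_text = row.get("lb", "").strip()
        ub_text = row.get("ub", "").strip()
        any_negative = any(c < 0 for c in stoich.values())
        any_positive = any(c > 0 for c in stoich.values())
        default_lb = DEFAULT_LOWER_BOUND if (any_negative and any_positive) else 0.0
        try:
            lb = float(lb_text) if lb_text else default_lb
            ub = float(ub_text) if ub_text else DEFAULT_UPPER_BOUND
        except ValueError as exc:
            raise TabularFormatError(f"line {line_no}: bad bound: {exc}") from exc
        reactions.append(Reaction(
            id=row["id"],
            name=row.get("name", "") or row["id"],
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=parse_gpr(row.get("gpr", "")),
            is_exchange=is_exchange or len(stoich) == 1,
            is_biomass=is_biomass,
        ))

    compartments = sorted({m.compartment for m in metabolites.values()}) or ["c"]
    model = MetabolicModel(
        model_id=model_id,
        compartments=compartments,
        metabolites=metabolites.values(),
        reactions=reactions,
        objective_id=objective,
    )
    for comp_id, rxn_id in registry.items():
        model.register_biomass(comp_id, rxn_id)
    return model


def write_tabular(model: MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    rxn_to_comp = {rid: cid for cid, rid in model.biomass_registry.items()}
    lines = [f"# model: {model.id}", "\t".join(COLUMNS)]
    for rxn in model.reactions.values():
        flags = []
        if rxn.is_exchange:
            flags.append("exchange")
        if rxn.id in rxn_to_comp:
            flags.append(f"biomass:{rxn_to_comp[rxn.id]}")
        elif rxn.is_biomass:
            flags.append("biomass")
        if rxn.id == model.objective_id:
            flags.append("objective")
        lines.append("\t".join([
            rxn.id,
            rxn.name,
            format_equation(rxn, model),
            f"{rxn.lower_bound:.17g}",
            f"{rxn.upper_bound:.17g}",
            rxn.gpr.to_string(),
            ",".join(flags),
        ]))
    path.write_text("\n".join(lines) + "\n")
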