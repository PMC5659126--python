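"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from scratch against the raw
model data structures — dense matrices, naive loops, exhaustive
enumeration — and never calls the implementation paths under test.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, Set, Tuple

import numpy as np
from scipy.optimize import linprog


def dense_lp(model, objective: str, sense: str = "max",
             extra_eq: Tuple[Dict[str, float], float] | None = None):
    """Solve the FBA LP from a dense from-scratch formulation.

    Returns (status, objective_value, flux dict).  ``extra_eq`` adds one
    equality row (coefficients by reaction id, rhs).
    """
    rxn_ids = sorted(model.reactions)  # different ordering than the package
    met_ids = sorted(model.metabolites)
    n, m = len(rxn_ids), len(met_ids)
    A = np.zeros((m, n))
    lb = np.empty(n)
    ub = np.empty(n)
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for met, coeff in rxn.stoichiometry.items():
            A[met_ids.index(met), j] = coeff
    b = np.zeros(m)
    if extra_eq is not None:
        coeffs, rhs = extra_eq
        row = np.zeros((1, n))
        for rid, c in coeffs.items():
            row[0, rxn_ids.index(rid)] = c
        A = np.vstack([A, row])
        b = np.append(b, rhs)
    c = np.zeros(n)
    c[rxn_ids.index(objective)] = -1.0 if sense == "max" else 1.0
    res = linprog(c, A_eq=A, b_eq=b, bounds=list(zip(lb, ub)),
                  method="highs-ds")
    if res.status == 2:
        return "infeasible", None, {}
    if res.status == 3:
        return "unbounded", None, {}
    assert res.status == 0, f"oracle LP status {res.status}"
    fluxes = dict(zip(rxn_ids, res.x))
    return "optimal", fluxes[objective], fluxes


def dense_fva(model, objective: str, gamma: float = 1.0):
    """Per-reaction [min, max] via one dense LP pair per reaction."""
    status, z, _ = dense_lp(model, objective, "max")
    assert status == "optimal"
    # fix the objective by tightening its lower bound (a formulation
    # different from the inequality row used by the implementation)
    work = model.copy()
    saved = work.reactions[objective].bounds
    work.reactions[objective].bounds = (
        max(saved[0], gamma * z - 1e-9), saved[1])
    out = {}
    for rid in work.reactions:
        _, lo, _ = dense_lp(work, rid, "min")
        _, hi, _ = dense_lp(work, rid, "max")
        out[rid] = (lo, hi)
    return out


def naive_gene_deletions(model, threshold: float = 1e-6) -> Dict[str, str]:
    """Phenotype every gene by naive reaction disabling + dense LP."""
    status, z0, _ = dense_lp(model, model.objective_id, "max")
    assert status == "optimal" and z0 > 0
    phenotypes = {}
    for gene in model.genes:
        work = model.copy()
        for rid, rxn in work.reactions.items():
            if gene in rxn.gpr.genes() and not truth_table_active(
                    rxn.gpr, {gene}):
                rxn.bounds = (0.0, 0.0)
        status, z, _ = dense_lp(work, work.objective_id, "max")
        grows = status == "optimal" and z is not None and z >= threshold
        phenotypes[gene] = "viable" if grows else "inviable"
    return phenotypes


def truth_table_active(expr, deleted: Iterable[str]) -> bool:
    """Evaluate a GPR tree by translating it to a Python boolean string."""
    deleted = set(deleted)

    def render(node) -> str:
        if node.kind == "empty":
            return "True"
        if node.kind == "gene":
            return "False" if node.gene in deleted else "True"
        op = " and " if node.kind == "and" else " or "
        return "(" + op.join(render(c) for c in node.children) + ")"

    return bool(eval(render(expr)))  # noqa: S307 - trusted literal


def enumerate_gpr_agreement(expr) -> bool:
    """Check tree evaluation against every deletion subset (<= 2^leaves)."""
    genes = sorted(expr.genes())
    for k in range(len(genes) + 1):
        for combo in itertools.combinations(genes, k):
            if expr.is_active(set(combo)) != truth_table_active(expr, combo):
                return False
    return True


def graph_dead_ends(model) -> Set[str]:
    """Dead-end metabolites from an explicit bipartite digraph."""
    import networkx as nx

    g = nx.DiGraph()
    for rid, rxn in model.reactions.items():
        if rxn.lower_bound == 0 and rxn.upper_bound == 0:
            continue
        rnode = ("rxn", rid)
        for met, coeff in rxn.stoichiometry.items():
            mnode = ("met", met)
            fwd = rxn.upper_bound > 0
            bwd = rxn.lower_bound < 0
            if coeff < 0:
                if fwd:
                    g.add_edge(mnode, rnode)   # consumed
                if bwd:
                    g.add_edge(rnode, mnode)   # produced in reverse
            elif coeff > 0:
                if fwd:
                    g.add_edge(rnode, mnode)
                if bwd:
                    g.add_edge(mnode, rnode)
    dead = set()
    for met in model.metabolites:
        mnode = ("met", met)
        produced = g.has_node(mnode) and g.in_degree(mnode) > 0
        consumed = g.has_node(mnode) and g.out_degree(mnode) > 0
        if not (produced and consumed):
            dead.add(met)
    return dead
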