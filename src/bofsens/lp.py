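"""Linear-programming core: flux balance analysis and flux variability analysis.

FBA solves ``max/min c.v  s.t.  S.v = 0,  lb <= v <= ub`` where S is the
stoichiometric matrix and c selects the objective reaction (biomass
maximisation in the standard workflow).  FVA fixes the objective at a
fraction gamma of its optimum and computes each reaction's attainable
``[v_min, v_max]`` — the "allowable range" used by the flux-sampling
significance procedure.

Solves use scipy's HiGHS interface.  Raw solver values are kept on the
result objects; user-facing serialisation rounds magnitudes below
``ZERO_FLUX_TOL`` (1e-5 mmol/gCDW/hr) to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import ConstraintSet, MetabolicModel

__all__ = [
    "FluxDistribution",
    "FluxRange",
    "ZERO_FLUX_TOL",
    "STEADY_STATE_TOL",
    "fba",
    "fva",
    "apply_constraints",
    "InfeasibleProblemError",
]

#: magnitudes below this are reported as zero in user-facing output
ZERO_FLUX_TOL = 1e-5
#: max allowed |S.v| residual for an accepted optimal solution
STEADY_STATE_TOL = 1e-6
#: slack subtracted from gamma * z_opt when fixing the objective in FVA,
#: guarding against infeasibility from solver round-off
OBJECTIVE_FIX_SLACK = 1e-9


class InfeasibleProblemError(RuntimeError):
    """Raised when a computation requires a feasible base problem."""


@dataclass
class FluxDistribution:
    """One FBA solution: a flux vector with its objective value and status."""

    fluxes: Dict[str, float]
    objective_value: Optional[float]
    status: str  # optimal | infeasible | unbounded
    objective_id: Optional[str] = None
    residual: float = 0.0

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    def rounded(self, tol: float = ZERO_FLUX_TOL) -> Dict[str, float]:
        """Fluxes with magnitudes below ``tol`` reported as zero."""
        return {k: (0.0 if abs(v) < tol else v) for k, v in self.fluxes.items()}


@dataclass
class FluxRange:
    """Per-reaction [min, max] flux at a fixed objective fraction gamma."""

    ranges: Dict[str, Tuple[float, float]]
    gamma: float = 1.0
    objective_id: Optional[str] = None
    objective_value: Optional[float] = None

    def __getitem__(self, reaction_id: str) -> Tuple[float, float]:
        return self.ranges[reaction_id]

    def span(self, reaction_id: str) -> float:
        lo, hi = self.ranges[reaction_id]
        return hi - lo


def _build_lp(model: MetabolicModel):
    """Assemble S (sparse), bounds, and the reaction index order."""
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    bounds = []
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        for met_id, coeff in rxn.stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(coeff)
        bounds.append((rxn.lower_bound, rxn.upper_bound))
    S = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(met_index), len(rxn_ids))
    )
    return S, bounds, rxn_ids


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


def fba(
    model: MetabolicModel,
    constraints: Optional[ConstraintSet] = None,
    objective: Optional[str] = None,
    sense: str = "max",
) -> FluxDistribution:
    """Flux balance analysis.

    Maximises (or minimises) the flux through ``objective`` (default: the
    model's objective reaction) subject to steady state and bounds, with
    the optional exchange-rate constraints applied to a working copy.
    """
    if constraints is not None:
        model = apply_constraints(model, constraints)
    objective = objective or model.objective_id
    if objective is None or objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")

    S, bounds, rxn_ids = _build_lp(model)
    c = np.zeros(len(rxn_ids))
    j_obj = rxn_ids.index(objective)
    c[j_obj] = -1.0 if sense == "max" else 1.0
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxDistribution(
            fluxes={}, objective_value=None, status=status, objective_id=objective
        )
    v = res.x
    residual = float(np.abs(S @ v).max()) if len(v) else 0.0
    if residual > STEADY_STATE_TOL:
        raise RuntimeError(
            f"steady-state residual {residual:.2e} exceeds {STEADY_STATE_TOL:.0e}"
        )
    return FluxDistribution(
        fluxes=dict(zip(rxn_ids, map(float, v))),
        objective_value=float(v[j_obj]),
        status="optimal",
        objective_id=objective,
        residual=residual,
    )


def fva(
    model: MetabolicModel,
    constraints: Optional[ConstraintSet] = None,
    objective: Optional[str] = None,
    gamma: float = 1.0,
    reactions: Optional[list] = None,
) -> FluxRange:
    """Flux variability analysis.

    For every reaction j, solves min and max of v_j subject to the FBA
    constraints plus ``c.v >= gamma * z_opt`` (z_opt from a preliminary
    FBA).  ``gamma`` in (0, 1]; 1.0 fixes the objective at its optimum.
    """
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    if constraints is not None:
        model = apply_constraints(model, constraints)
    base = fba(model, None, objective=objective)
    if not base.optimal:
        raise InfeasibleProblemError(
            f"FVA base problem is {base.status}; cannot fix objective"
        )
    objective = base.objective_id
    S, bounds, rxn_ids = _build_lp(model)
    j_obj = rxn_ids.index(objective)
    n = len(rxn_ids)
    # objective fixing as inequality: -v_obj <= -(gamma * z_opt - slack)
    A_ub = sparse.csr_matrix(
        (np.array([-1.0]), (np.array([0]), np.array([j_obj]))), shape=(1, n)
    )
    b_ub = np.array([-(gamma * base.objective_value - OBJECTIVE_FIX_SLACK)])
    b_eq = np.zeros(S.shape[0])

    targets = reactions if reactions is not None else rxn_ids
    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        j = rxn_ids.index(rid)
        c = np.zeros(n)
        extrema = []
        for sign in (1.0, -1.0):  # min then max
            c[j] = sign
            res = linprog(
                c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=b_eq,
                bounds=bounds, method="highs",
            )
            if res.status != 0:
                raise InfeasibleProblemError(
                    f"FVA subproblem for {rid!r} returned status {res.status}"
                )
            extrema.append(float(res.x[j]))
        c[j] = 0.0
        lo, hi = extrema
        if lo > hi:  # solver round-off on a degenerate range
            lo = hi = 0.5 * (lo + hi)
        ranges[rid] = (lo, hi)
    return FluxRange(
        ranges=ranges,
        gamma=gamma,
        objective_id=objective,
        objective_value=base.objective_value,
    )


def apply_constraints(
    model: MetabolicModel, constraints: ConstraintSet
) -> MetabolicModel:
    """Return a model copy with exchange bounds set from measured rates.

    Uptake magnitude ``u`` fixes the exchange at (-u, -u); secretion
    ``s`` enforces (s, 1000).  The input model is untouched.
    """
    constraints.validate_against(model)
    out = model.copy()
    for rxn_id, bnds in constraints.bounds_map().items():
        out.reactions[rxn_id].bounds = bnds
    return out
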