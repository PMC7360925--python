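"""Flux balance analysis on organism and community models.

The LP core is deliberately small: steady state ``S·v = 0``, flux bounds
``lb ≤ v ≤ ub`` (fixed demands are pinned ``lb = ub``), and a linear
objective.  Degenerate optima are resolved by parsimonious FBA (pFBA):
minimize total absolute flux ``Σ|v|`` via the standard ``t ≥ ±v`` epigraph
splitting, which yields a unique, economical flux distribution on the
networks this package targets.

The solver back end sits behind :func:`_solve_lp`; the default is scipy's
HiGHS interface (dual simplex, deterministic).  Feasibility tolerance is
HiGHS's default (1e-9 scale); mass-balance reporting uses ``ε = 1e-6``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .community import CommunityModel
from .core import OrganismModel, stoichiometric_matrix
from .errors import ConfigurationError, InfeasibleError

#: componentwise mass-balance reporting tolerance, mmol·gDW⁻¹·h⁻¹
BALANCE_EPS = 1e-6

Status = Literal["optimal", "infeasible", "unbounded"]


@dataclass(frozen=True)
class FluxSolution:
    status: Status
    objective_value: float
    fluxes: dict[str, float]

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def require_optimal(self) -> "FluxSolution":
        if self.status != "optimal":
            raise InfeasibleError(f"LP status is {self.status!r}, not optimal")
        return self


@dataclass(frozen=True)
class FVAResult:
    gamma: float
    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]


def _as_model(community: CommunityModel | OrganismModel) -> tuple[OrganismModel, dict[str, float]]:
    if isinstance(community, CommunityModel):
        return community.model, dict(community.fixed_demands)
    return community, {}


def _problem_arrays(model: OrganismModel, fixed_demands: Mapping[str, float]):
    """(S, lb, ub, rxn_ids) with fixed demands pinned into the bounds."""
    smat = stoichiometric_matrix(model)
    n = len(smat.rxn_ids)
    lb = np.empty(n)
    ub = np.empty(n)
    for j, rid in enumerate(smat.rxn_ids):
        rx = model.reactions[rid]
        lb[j], ub[j] = rx.lb, rx.ub
        if rid in fixed_demands:
            lb[j] = ub[j] = fixed_demands[rid]
    return smat, lb, ub


_STATUS_MAP = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve_lp(c, A_ub, b_ub, A_eq, b_eq, bounds) -> tuple[Status, np.ndarray | None, float]:
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS_MAP.get(res.status)
    if status is None:  # iteration/numerical trouble: surface, never silent zeros
        raise InfeasibleError(f"LP solver failed: {res.message}")
    if status != "optimal":
        return status, None, float("nan")
    return "optimal", res.x, float(res.fun)


def solve_fba(
    community: CommunityModel | OrganismModel,
    objective: Mapping[str, float] | None = None,
    sense: Literal["max", "min"] = "max",
) -> FluxSolution:
    """Optimize a linear flux objective at steady state.

    ``objective`` maps reaction id → weight; ``None`` uses the model's own
    objective (which may be empty, reducing FBA to a feasibility check).
    Infeasibility/unboundedness is reported in ``status``, never as zeros.
    """
    model, fixed = _as_model(community)
    if objective is None:
        objective = model.objective
    smat, lb, ub = _problem_arrays(model, fixed)
    n = len(smat.rxn_ids)
    c = np.zeros(n)
    ridx = smat.rxn_index
    for rid, w in objective.items():
        if rid not in ridx:
            raise ConfigurationError(f"objective reaction {rid!r} not in model")
        c[ridx[rid]] = w
    sign = -1.0 if sense == "max" else 1.0
    status, x, fun = _solve_lp(
        sign * c, None, None, smat.matrix, np.zeros(smat.matrix.shape[0]),
        list(zip(lb, ub)),
    )
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"), fluxes={})
    return FluxSolution(
        status="optimal",
        objective_value=sign * fun,
        fluxes={rid: float(x[j]) for j, rid in enumerate(smat.rxn_ids)},
    )


def _pfba_arrays(smat, lb, ub):
    """Variables [v; t], min Σt s.t. S v = 0, v − t ≤ 0, −v − t ≤ 0."""
    n = smat.matrix.shape[1]
    m = smat.matrix.shape[0]
    A_eq = sp.hstack([smat.matrix, sp.csr_matrix((m, n))], format="csr")
    I = sp.identity(n, format="csr")
    A_ub = sp.vstack([sp.hstack([I, -I]), sp.hstack([-I, -I])], format="csr")
    b_ub = np.zeros(2 * n)
    tmax = np.maximum(np.abs(lb), np.abs(ub))
    bounds = list(zip(lb, ub)) + list(zip(np.zeros(n), tmax))
    c = np.concatenate([np.zeros(n), np.ones(n)])
    return c, A_ub, b_ub, A_eq, np.zeros(m), bounds


def solve_pfba(
    community: CommunityModel | OrganismModel,
    objective: Mapping[str, float] | None = None,
    sense: Literal["max", "min"] = "max",
) -> FluxSolution:
    """Parsimonious FBA: the minimal-total-flux distribution.

    With a nonempty ``objective`` the objective is first optimized and then
    pinned while ``Σ|v|`` is minimized; with no objective (the fixed-demand
    communities this package centres on) it is a single minimization.  The
    reported ``objective_value`` is the pFBA total flux.
    """
    model, fixed = _as_model(community)
    if objective is None:
        objective = model.objective
    smat, lb, ub = _problem_arrays(model, fixed)
    if objective:
        stage1 = solve_fba(community, objective=objective, sense=sense)
        if stage1.status != "optimal":
            return stage1
        # pin the achieved optimum as an equality row over the objective reactions
        ridx = smat.rxn_index
        row = np.zeros(len(smat.rxn_ids))
        for rid, w in objective.items():
            row[ridx[rid]] = w
        extra_eq = (row, stage1.objective_value)
    else:
        extra_eq = None

    c, A_ub, b_ub, A_eq, b_eq, bounds = _pfba_arrays(smat, lb, ub)
    if extra_eq is not None:
        row, val = extra_eq
        n = len(smat.rxn_ids)
        A_eq = sp.vstack([A_eq, sp.csr_matrix(np.concatenate([row, np.zeros(n)]))], format="csr")
        b_eq = np.concatenate([b_eq, [val]])
    status, x, fun = _solve_lp(c, A_ub, b_ub, A_eq, b_eq, bounds)
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"), fluxes={})
    n = len(smat.rxn_ids)
    return FluxSolution(
        status="optimal",
        objective_value=float(fun),
        fluxes={rid: float(x[j]) for j, rid in enumerate(smat.rxn_ids)},
    )


def flux_variability(
    community: CommunityModel | OrganismModel,
    reactions: Sequence[str],
    gamma: float = 0.0,
) -> FVAResult:
    """Min/max flux per listed reaction within the pFBA flux envelope.

    The envelope is ``Σ|v| ≤ (1 + γ) × pFBA optimum``: γ = 0 asks how
    determined each flux is at strict parsimony; larger γ relaxes it.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    model, fixed = _as_model(community)
    base = solve_pfba(community, objective={})
    base.require_optimal()
    smat, lb, ub = _problem_arrays(model, fixed)
    c0, A_ub, b_ub, A_eq, b_eq, bounds = _pfba_arrays(smat, lb, ub)
    n = len(smat.rxn_ids)
    # add the envelope row: sum(t) <= (1+gamma) * optimum
    env = np.concatenate([np.zeros(n), np.ones(n)])
    A_ub = sp.vstack([A_ub, sp.csr_matrix(env)], format="csr")
    b_ub = np.concatenate([b_ub, [(1.0 + gamma) * base.objective_value]])
    ridx = smat.rxn_index
    ranges: dict[str, tuple[float, float]] = {}
    for rid in reactions:
        if rid not in ridx:
            raise ConfigurationError(f"FVA reaction {rid!r} not in model")
        c = np.zeros(2 * n)
        c[ridx[rid]] = 1.0
        lo_status, lo_x, lo = _solve_lp(c, A_ub, b_ub, A_eq, b_eq, bounds)
        hi_status, hi_x, hi = _solve_lp(-c, A_ub, b_ub, A_eq, b_eq, bounds)
        if lo_status != "optimal" or hi_status != "optimal":
            raise InfeasibleError(f"FVA subproblem for {rid!r} not optimal")
        ranges[rid] = (float(lo), float(-hi))
    return FVAResult(gamma=gamma, ranges=ranges)


def check_balance(
    community: CommunityModel | OrganismModel,
    solution: FluxSolution,
    eps: float = BALANCE_EPS,
) -> dict[str, float]:
    """Metabolites whose net production |S·v| exceeds ``eps``.

    Empty dict = mass-balanced solution.  Useful as a cheap independent
    audit of any flux vector, including hand-edited ones.
    """
    solution.require_optimal()
    model, _ = _as_model(community)
    smat = stoichiometric_matrix(model)
    v = np.array([solution.fluxes.get(rid, 0.0) for rid in smat.rxn_ids])
    residual = smat.matrix @ v
    return {
        met: float(residual[i])
        for i, met in enumerate(smat.met_ids)
        if abs(residual[i]) > eps
    }
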