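"""Flux balance analysis: maximize biomass flux under steady state.

The linear program is the standard one: choose a flux vector v maximizing
the biomass flux v_bio subject to S·v = 0 (every metabolite produced as
fast as it is consumed) and per-reaction bounds l_r ≤ v_r ≤ u_r. Unbounded
flux directions are capped with a large scalar M. Gene knockouts enter by
clamping the bounds of their disabled reactions to [0, 0].

The solver backend is pluggable behind a single solve-LP contract; the
default is HiGHS via :func:`scipy.optimize.linprog`. Any two supported
backends must agree on the objective within ``opt_tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, ModelValidationError

__all__ = ["SolverConfig", "FluxSolution", "SolverError", "maximize_biomass", "apply_medium"]

#: linprog methods accepted as backends (all HiGHS variants: simplex dual,
#: interior point, and the automatic chooser).
BACKENDS = ("highs", "highs-ds", "highs-ipm")


class SolverError(RuntimeError):
    """LP solver failed for a reason other than infeasible/unbounded."""

    def __init__(self, message: str, solver_status: object = None):
        super().__init__(message)
        self.solver_status = solver_status


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration for the biomass LP.

    big_M caps unbounded flux directions (mmol·gDW⁻¹·h⁻¹); feas_tol and
    opt_tol are the feasibility/optimality tolerances, both far below the
    1e-4 gDW/h essentiality threshold so lethality calls never hinge on
    solver noise. Objective values within ±opt_tol of zero are reported as
    exactly 0.
    """

    big_M: float = 1000.0
    feas_tol: float = 1e-9
    opt_tol: float = 1e-9
    backend: str = "highs"

    def __post_init__(self):
        if self.big_M <= 0:
            raise ValueError("big_M must be positive")
        if self.feas_tol <= 0 or self.opt_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}; choose from {BACKENDS}")


DEFAULT_CONFIG = SolverConfig()


@dataclass(frozen=True)
class FluxSolution:
    """Outcome of a biomass maximization.

    ``objective`` is the maximal biomass flux v_bio (gDW/h); ``fluxes`` maps
    each reaction id to its flux in the optimal solution. When the status is
    not ``optimal`` the objective is NaN and fluxes are empty.
    """

    status: str  # optimal | infeasible | unbounded
    objective: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _effective_bounds(
    model: MetabolicModel, disabled: frozenset[str], config: SolverConfig
) -> list[tuple[float, float]]:
    M = config.big_M
    bounds = []
    for r in model.reactions:
        if r.id in disabled:
            bounds.append((0.0, 0.0))
            continue
        lb = max(r.lower_bound, -M) if r.reversible else max(r.lower_bound, 0.0, -M)
        ub = min(r.upper_bound, M)
        bounds.append((lb, ub))
    return bounds


def maximize_biomass(
    model: MetabolicModel,
    disabled_reactions: Iterable[str] = (),
    config: SolverConfig = DEFAULT_CONFIG,
) -> FluxSolution:
    """Solve max v_bio s.t. S·v = 0, l ≤ v ≤ u, disabled reactions at zero.

    Every optimal solution is re-checked against the mass-balance residuals
    and bounds (within ``feas_tol`` scaled by the largest flux magnitude)
    before it is returned — a cheap certificate that the solver's answer is
    a genuine steady-state flux distribution.
    """
    disabled = frozenset(disabled_reactions)
    unknown = [rid for rid in disabled if not model.has_reaction(rid)]
    if unknown:
        raise ModelValidationError(
            [f"disabled reaction {rid!r} is not in the model" for rid in sorted(unknown)]
        )
    if not model.biomass_reaction_id or not model.has_reaction(model.biomass_reaction_id):
        raise ModelValidationError(["model has no biomass reaction"])

    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    bounds = _effective_bounds(model, disabled, config)
    c = np.zeros(n)
    bio_j = next(
        j for j, r in enumerate(model.reactions) if r.id == model.biomass_reaction_id
    )
    c[bio_j] = -1.0  # linprog minimizes

    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method=config.backend,
        options={
            "primal_feasibility_tolerance": 1e-10,
            "dual_feasibility_tolerance": 1e-10,
        },
    )
    if res.status == 2:
        return FluxSolution(status="infeasible", objective=float("nan"))
    if res.status == 3:
        return FluxSolution(status="unbounded", objective=float("nan"))
    if res.status != 0:
        raise SolverError(f"LP solver failed: {res.message}", res.status)

    v = np.asarray(res.x)
    scale = max(1.0, float(np.max(np.abs(v))))
    tol = config.feas_tol * scale
    residual = float(np.max(np.abs(S @ v))) if S.size else 0.0
    if residual > tol:
        raise SolverError(
            f"solution violates mass balance: max residual {residual:.3e} > {tol:.3e}"
        )
    for (lb, ub), vr in zip(bounds, v):
        if vr < lb - tol or vr > ub + tol:
            raise SolverError("solution violates flux bounds")

    obj = float(v[bio_j])
    if abs(obj) <= config.opt_tol:
        obj = 0.0
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    return FluxSolution(status="optimal", objective=obj, fluxes=fluxes)


def apply_medium(model: MetabolicModel, medium: Mapping[str, float]) -> MetabolicModel:
    """Return a copy with exchange uptake bounds set from a growth medium.

    ``medium`` maps exchange reaction ids to the maximal intake flux of the
    corresponding nutrient (positive numbers). With the ``met -> ∅``
    exchange convention, intake is negative flux, so a listed exchange gets
    lower bound ``-medium[id]``; every unlisted exchange gets lower bound 0
    (nutrient absent — intake fixed to zero, secretion still allowed).
    """
    from dataclasses import replace

    bad = [
        rid
        for rid in medium
        if not model.has_reaction(rid) or not model.reaction(rid).is_exchange
    ]
    if bad:
        raise ModelValidationError(
            [f"medium key {rid!r} is not an exchange reaction" for rid in sorted(bad)]
        )
    out = model.copy()
    for r in out.exchange_reactions():
        uptake = float(medium.get(r.id, 0.0))
        if uptake < 0:
            raise ModelValidationError(
                [f"medium intake for {r.id!r} must be non-negative"]
            )
        new_lb = -uptake
        out.replace_reaction(
            replace(r, lower_bound=new_lb, reversible=new_lb < 0 or r.reversible)
        )
    out.medium = {k: float(v) for k, v in medium.items()}
    return out


def export_fluxes_tsv(solution: FluxSolution, path) -> None:
    """Debug export: one (reaction id, flux) row per reaction, tab-separated."""
    from pathlib import Path

    lines = ["reaction\tflux"]
    for rid in sorted(solution.fluxes):
        lines.append(f"{rid}\t{solution.fluxes[rid]:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")
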