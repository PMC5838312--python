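"""Linear-programming engine: FBA, FVA, NGAM estimation and sensitivity.

All solves go through scipy's HiGHS interface with a fixed, single-threaded
configuration so results are reproducible bit-for-bit on one platform.
Every optimal solution is audited against ``S·v = 0`` (residual ≤ 1e-6)
before being returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .constraints import PhaseConstraintSet
from .network import MetabolicNetwork, stoichiometric_matrix

FEASIBILITY_TOL = 1e-9
RESIDUAL_TOL = 1e-6


class InfeasibleModelError(RuntimeError):
    """The constrained LP admits no feasible flux distribution."""


class UnboundedModelError(RuntimeError):
    """The requested optimum is unbounded."""


@dataclass
class FluxDistribution:
    """One steady-state flux vector together with its objective value."""

    fluxes: Dict[str, float]
    objective_id: str
    objective_value: float
    solver_status: str
    residual: float = 0.0

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def vector(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in order])


@dataclass
class FVARange:
    """Per-reaction (min, max) flux under fixed constraints."""

    ranges: Dict[str, Tuple[float, float]]

    def __getitem__(self, rxn_id: str) -> Tuple[float, float]:
        return self.ranges[rxn_id]

    def span(self, rxn_id: str) -> float:
        lo, hi = self.ranges[rxn_id]
        return hi - lo


@dataclass
class NGAMResult:
    ngam: float
    biomass_error: float  # relative, as a fraction
    scan: List[Tuple[float, float, float]]  # (ngam, predicted_mu, error)
    grid: Tuple[float, float, float]  # (lo, hi, step)


@dataclass
class SensitivityReport:
    baseline_ngam: float
    per_rate: Dict[str, Tuple[float, float, float]]  # rid -> (+1%, -1%, change %)
    max_change: float
    max_change_rate: Optional[str] = None


class LinearModel:
    """Cached LP arrays for one network; cheap repeated solves."""

    def __init__(self, network: MetabolicNetwork):
        self.network = network
        self.S = stoichiometric_matrix(network)
        self.lb, self.ub = network.bounds()
        self.reaction_ids = network.reaction_ids
        self._index = {r: i for i, r in enumerate(self.reaction_ids)}

    def index(self, rxn_id: str) -> int:
        return self._index[rxn_id]

    def solve(
        self,
        objective: Mapping[str, float],
        sense: str = "max",
        bound_overrides: Optional[Mapping[str, Tuple[float, float]]] = None,
    ) -> Tuple[str, Optional[np.ndarray], float]:
        """Return (status, x, objective_value); status in
        {optimal, infeasible, unbounded}."""
        m = len(self.reaction_ids)
        c = np.zeros(m)
        for rid, coeff in objective.items():
            c[self._index[rid]] = coeff
        if sense == "max":
            c = -c
        elif sense != "min":
            raise ValueError("sense must be 'max' or 'min'")
        lb = self.lb.copy()
        ub = self.ub.copy()
        if bound_overrides:
            for rid, (lo, hi) in bound_overrides.items():
                i = self._index[rid]
                lb[i], ub[i] = lo, hi
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
            options={"presolve": True},
        )
        if res.status == 0:
            value = float(-res.fun) if sense == "max" else float(res.fun)
            return "optimal", res.x, value
        if res.status == 2:
            return "infeasible", None, float("nan")
        if res.status == 3:
            return "unbounded", None, float("nan")
        raise RuntimeError(f"LP solver failure: {res.message}")  # pragma: no cover

    def audit(self, x: np.ndarray) -> float:
        return float(np.max(np.abs(self.S @ x))) if x is not None else float("nan")


def solve_fba(
    network: MetabolicNetwork,
    objective_id: Optional[str] = None,
    sense: str = "max",
) -> FluxDistribution:
    """Optimize one reaction flux subject to ``S·v = 0`` and the bounds."""
    objective_id = objective_id or network.objective_id
    if objective_id is None:
        raise ValueError("no objective reaction specified")
    lp = LinearModel(network)
    status, x, value = lp.solve({objective_id: 1.0}, sense=sense)
    if status != "optimal":
        return FluxDistribution({}, objective_id, float("nan"), status)
    residual = lp.audit(x)
    if residual > RESIDUAL_TOL:  # pragma: no cover - solver guarantee
        raise RuntimeError(f"steady-state residual {residual:.2e} exceeds tolerance")
    fluxes = dict(zip(lp.reaction_ids, map(float, x)))
    return FluxDistribution(fluxes, objective_id, value, "optimal", residual)


def solve_fva(
    network: MetabolicNetwork,
    reaction_ids: Optional[Iterable[str]] = None,
) -> FVARange:
    """Per-reaction min/max flux under the network's constraints.

    The main objective is *not* fixed at its optimum: the experimental data
    embedded in the bounds are the only constraints.
    """
    lp = LinearModel(network)
    ids = list(reaction_ids) if reaction_ids is not None else lp.reaction_ids
    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in ids:
        lo = _single_opt(lp, rid, "min")
        hi = _single_opt(lp, rid, "max")
        ranges[rid] = (lo, hi)
    return FVARange(ranges)


def _single_opt(lp: LinearModel, rxn_id: str, sense: str) -> float:
    status, _, value = lp.solve({rxn_id: 1.0}, sense=sense)
    if status == "infeasible":
        raise InfeasibleModelError(f"model infeasible while optimizing {rxn_id}")
    if status == "unbounded":
        raise UnboundedModelError(f"{sense} of {rxn_id} is unbounded")
    return value


def fva_linear_combination(
    network: MetabolicNetwork,
    reaction_ids: Sequence[str],
    coefficients: Sequence[float],
) -> Tuple[float, float]:
    """(min, max) of ``sum(c_i · v_i)`` under all current constraints."""
    if len(reaction_ids) != len(coefficients):
        raise ValueError("reaction_ids and coefficients differ in length")
    lp = LinearModel(network)
    objective = dict(zip(reaction_ids, coefficients))
    lo_status, _, lo = lp.solve(objective, sense="min")
    hi_status, _, hi = lp.solve(objective, sense="max")
    for status in (lo_status, hi_status):
        if status == "infeasible":
            raise InfeasibleModelError("constrained model infeasible")
        if status == "unbounded":
            raise UnboundedModelError("linear combination unbounded")
    return lo, hi


def estimate_ngam(
    network: MetabolicNetwork,
    constraints: PhaseConstraintSet,
    mu_experimental: float,
    grid_step: float = 0.01,
    grid_max: float = 4.0,
    coarse_step: Optional[float] = None,
    ngam_id: str = "NGAM",
    biomass_id: str = "BIOMASS",
) -> NGAMResult:
    """Grid-scan the maintenance flux and pick the biomass-error minimizer.

    For each NGAM value on ``[0, grid_max]`` the maintenance reaction is
    fixed, biomass production is maximized, and the relative prediction
    error ``|mu_pred - mu_exp| / mu_exp`` recorded.  Ties break toward the
    smallest NGAM.  With ``coarse_step`` the scan runs in two stages: a
    coarse pass over the full grid, then a ``grid_step`` pass in the
    winning coarse cell (same estimator, cheaper when grid_step is fine).
    """
    if mu_experimental <= 0:
        raise ValueError("mu_experimental must be positive")
    constrained = constraints.apply(network, biomass_id=biomass_id, ngam_id=ngam_id)
    # biomass is the scan objective, not a constraint here
    constrained.set_bounds(biomass_id, 0.0, network.reaction(biomass_id).upper_bound)
    lp = LinearModel(constrained)

    scan: List[Tuple[float, float, float]] = []

    def run_scan(lo: float, hi: float, step: float):
        best = None
        n_steps = int(round((hi - lo) / step))
        for k in range(n_steps + 1):
            g = round(lo + k * step, 12)
            status, x, mu_pred = lp.solve(
                {biomass_id: 1.0}, sense="max",
                bound_overrides={ngam_id: (g, g)},
            )
            if status != "optimal":
                continue
            err = abs(mu_pred - mu_experimental) / mu_experimental
            scan.append((g, mu_pred, err))
            if best is None or err < best[2] - FEASIBILITY_TOL:
                best = (g, mu_pred, err)
        return best

    if coarse_step is not None and coarse_step > grid_step:
        best = run_scan(0.0, grid_max, coarse_step)
        if best is not None:
            lo = max(0.0, best[0] - coarse_step)
            hi = min(grid_max, best[0] + coarse_step)
            fine = run_scan(lo, hi, grid_step)
            if fine is not None and fine[2] < best[2] - FEASIBILITY_TOL:
                best = fine
            elif fine is not None and fine[0] < best[0] and fine[2] <= best[2] + FEASIBILITY_TOL:
                best = fine
    else:
        best = run_scan(0.0, grid_max, grid_step)
    if best is None:
        raise InfeasibleModelError(
            "no feasible NGAM grid point in "
            f"[0, {grid_max}] under the given constraints"
        )
    return NGAMResult(
        ngam=best[0],
        biomass_error=best[2],
        scan=sorted(scan),
        grid=(0.0, grid_max, grid_step),
    )


def ngam_sensitivity(
    network: MetabolicNetwork,
    constraints: PhaseConstraintSet,
    mu_experimental: float,
    perturbation: float = 0.01,
    grid_step: float = 0.01,
    grid_max: float = 4.0,
    coarse_step: Optional[float] = None,
    ngam_id: str = "NGAM",
    biomass_id: str = "BIOMASS",
) -> SensitivityReport:
    """Re-estimate NGAM with each fixed rate perturbed by ±``perturbation``.

    The headline ``max_change`` is the largest relative NGAM change (%)
    over all rates and both signs.
    """
    baseline = estimate_ngam(
        network, constraints, mu_experimental,
        grid_step=grid_step, grid_max=grid_max, coarse_step=coarse_step,
        ngam_id=ngam_id, biomass_id=biomass_id,
    )
    per_rate: Dict[str, Tuple[float, float, float]] = {}
    max_change = 0.0
    max_rate: Optional[str] = None
    denom = max(abs(baseline.ngam), grid_step)
    for rid, value in constraints.fixed_fluxes.items():
        results = []
        for sign in (+1.0, -1.0):
            pert = PhaseConstraintSet(
                phase_id=constraints.phase_id,
                fixed_fluxes={
                    **constraints.fixed_fluxes,
                    rid: value * (1.0 + sign * perturbation),
                },
                biomass=constraints.biomass,
                ngam=None,
                tolerance=constraints.tolerance,
                range_bounds=dict(constraints.range_bounds),
            )
            try:
                est = estimate_ngam(
                    network, pert, mu_experimental,
                    grid_step=grid_step, grid_max=grid_max,
                    coarse_step=coarse_step,
                    ngam_id=ngam_id, biomass_id=biomass_id,
                )
                results.append(est.ngam)
            except InfeasibleModelError:
                results.append(float("nan"))
        plus, minus = results
        deltas = [
            abs(v - baseline.ngam) for v in results if not np.isnan(v)
        ]
        change = 100.0 * max(deltas) / denom if deltas else float("nan")
        per_rate[rid] = (plus, minus, change)
        if not np.isnan(change) and change > max_change:
            max_change = change
            max_rate = rid
    return SensitivityReport(
        baseline_ngam=baseline.ngam,
        per_rate=per_rate,
        max_change=max_change,
        max_change_rate=max_rate,
    )
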