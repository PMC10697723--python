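"""Constraint-based flux analysis: measured-rate bounds, LP solve, ensemble.

The steady-state assumption S·v = 0 with flux bounds lb <= v <= ub defines a
polytope; flux balance analysis maximizes an objective reaction (here HA
synthesis) over it. Measured exchange rates enter as interval bounds
[rate - k·SD, rate + k·SD] on the matching exchange reactions; growth is
lower-bounded by the measured growth rate and O2 exchange bounded by the
respirometry-derived rate. Because LP optima are generally degenerate, a
parsimonious second stage minimizes total absolute flux at the fixed optimal
objective so that per-reaction fluxes are well-defined for condition
comparisons.

Measurement uncertainty is propagated by a constraint-resampling ensemble:
each of n runs redraws every measured rate from a truncated normal (truncated
to the network's default bounds), rebuilds the interval bounds around the
draw, and re-solves.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.stats import truncnorm

from .exceptions import ConstraintError, NetworkError
from .fluxomics import (
    DEFAULT_GDW_PER_CELL,
    ExchangeRate,
    fmol_per_cell_h_to_mmol_per_gdw_h,
)
from .network import MetabolicNetwork

__all__ = [
    "ConstraintSet",
    "FluxSolution",
    "FluxEnsemble",
    "DEFAULT_OMITTED_AMINO_ACIDS",
    "BIOENERGETIC_TAGS",
    "build_constraints",
    "solve_fba",
    "ensemble_fba",
    "compare_conditions",
]

logger = logging.getLogger(__name__)

#: Amino acids whose exchange constraints are omitted (kept at default
#: network bounds) so that the LP remains well-behaved.
DEFAULT_OMITTED_AMINO_ACIDS: Tuple[str, ...] = (
    "glycine", "leucine", "lysine", "phenylalanine",
    "threonine", "tryptophan", "tyrosine", "valine",
)

#: Tags of the bioenergetic reaction subset used for condition comparison.
BIOENERGETIC_TAGS: Tuple[str, ...] = (
    "upper_glycolysis", "pyruvate_to_lactate", "glutamate_to_akg",
    "akg_to_succinylcoa", "ATP_demand", "HA_synthesis", "O2_exchange",
)

_FEAS_TOL = 1e-9


@dataclass(frozen=True)
class ConstraintSet:
    """Exchange/growth/O2 bounds in model units, with provenance."""

    exchange_bounds: Mapping[str, Tuple[float, float]]  # rxn id -> (lb, ub)
    omitted_metabolites: Tuple[str, ...]
    growth_bounds: Optional[Tuple[float, Optional[float]]] = None
    o2_bounds: Optional[Tuple[float, float]] = None
    provenance: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    #: (rate, sd) in model units per constrained exchange reaction id

    def apply(self, net: MetabolicNetwork) -> Tuple[np.ndarray, np.ndarray]:
        """Default network bounds overridden by this constraint set."""
        lb, ub = net.bounds()
        for rxn_id, (lo, hi) in self.exchange_bounds.items():
            j = net.reaction_index(rxn_id)
            lb[j], ub[j] = lo, hi
        if self.o2_bounds is not None:
            for rxn_id in net.tagged("O2_exchange"):
                j = net.reaction_index(rxn_id)
                lb[j], ub[j] = self.o2_bounds
        if self.growth_bounds is not None:
            lo, hi = self.growth_bounds
            for rxn_id in net.tagged("growth"):
                j = net.reaction_index(rxn_id)
                lb[j] = lo
                if hi is not None:
                    ub[j] = hi
        if np.any(lb > ub):
            bad = [net.reaction_ids[j] for j in np.nonzero(lb > ub)[0]]
            raise ConstraintError(f"constraints produce lb > ub for {bad}")
        return lb, ub


@dataclass(frozen=True)
class FluxSolution:
    fluxes: Optional[pd.Series]      # per-reaction values, None unless optimal
    objective_value: Optional[float]
    status: str                      # "optimal" | "infeasible" | "unbounded"


@dataclass(frozen=True)
class FluxEnsemble:
    condition: str
    n_runs: int
    fluxes: pd.DataFrame             # optimal rows only, columns = reactions
    seed: int
    infeasible_count: int
    network_reactions: Tuple[str, ...]
    #: per optimal row, the (lb, ub) arrays actually used for that solve
    drawn_bounds: Tuple[Tuple[np.ndarray, np.ndarray], ...] = ()


def _clip_interval(lo: float, hi: float, default_lo: float, default_hi: float):
    return max(lo, default_lo), min(hi, default_hi)


def build_constraints(
    rates: Mapping[str, ExchangeRate],
    net: MetabolicNetwork,
    omit: Sequence[str] = DEFAULT_OMITTED_AMINO_ACIDS,
    k_sd: float = 1.0,
    gdw_per_cell: float = DEFAULT_GDW_PER_CELL,
    rates_in_model_units: bool = False,
    growth_rate: Optional[float] = None,
    growth_rate_sd: float = 0.0,
    o2_rate: Optional[float] = None,
    o2_rate_sd: float = 0.0,
) -> ConstraintSet:
    """Map measured exchange rates onto network exchange bounds.

    Parameters
    ----------
    rates:
        metabolite name -> :class:`ExchangeRate` (fmol/cell/h unless
        ``rates_in_model_units``). Positive = secretion, matching the model's
        exchange convention.
    omit:
        Metabolites left at default network bounds even when measured.
    k_sd:
        Half-width of the bound interval in SD units.
    growth_rate:
        Measured growth rate (1/h); becomes the growth-reaction lower bound
        (growth is required, not maximized).
    o2_rate:
        O2 exchange rate in model units (negative = consumption), typically
        derived from respirometry; bounded like a measured exchange.
    """
    exchange_map = net.exchange_map
    omit_set = set(omit)
    bounds: Dict[str, Tuple[float, float]] = {}
    provenance: Dict[str, Tuple[float, float]] = {}
    missing: List[str] = []
    for name, measured in rates.items():
        if name in omit_set:
            continue
        if name not in exchange_map:
            missing.append(name)
            continue
        rxn_id = exchange_map[name]
        rxn = net.reaction(rxn_id)
        if rates_in_model_units:
            rate, sd = measured.rate, measured.rate_sd
        else:
            rate = fmol_per_cell_h_to_mmol_per_gdw_h(measured.rate, gdw_per_cell)
            sd = fmol_per_cell_h_to_mmol_per_gdw_h(measured.rate_sd, gdw_per_cell)
        lo, hi = _clip_interval(rate - k_sd * sd, rate + k_sd * sd, rxn.lb, rxn.ub)
        if lo > hi:
            raise ConstraintError(
                f"measured rate for {name} ({rate:g} ± {sd:g}) lies outside the "
                f"default bounds of {rxn_id} [{rxn.lb}, {rxn.ub}]"
            )
        bounds[rxn_id] = (lo, hi)
        provenance[rxn_id] = (rate, sd)
    if missing:
        raise ConstraintError(
            f"measured metabolites with no exchange reaction: {sorted(missing)}"
        )
    o2_bounds = None
    if o2_rate is not None:
        o2_ids = net.tagged("O2_exchange")
        rxn = net.reaction(o2_ids[0])
        o2_bounds = _clip_interval(
            o2_rate - k_sd * o2_rate_sd, o2_rate + k_sd * o2_rate_sd, rxn.lb, rxn.ub
        )
        provenance = {**provenance, o2_ids[0]: (o2_rate, o2_rate_sd)}
    growth_bounds = None
    if growth_rate is not None:
        growth_bounds = (max(growth_rate - k_sd * growth_rate_sd, 0.0), None)
    return ConstraintSet(
        exchange_bounds=bounds,
        omitted_metabolites=tuple(sorted(omit_set)),
        growth_bounds=growth_bounds,
        o2_bounds=o2_bounds,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# LP solving
# ---------------------------------------------------------------------------

def _linprog_solve(c, A_eq, b_eq, lb, ub, A_ub=None, b_ub=None):
    return linprog(
        c,
        A_eq=A_eq, b_eq=b_eq,
        A_ub=A_ub, b_ub=b_ub,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": _FEAS_TOL,
                 "dual_feasibility_tolerance": _FEAS_TOL},
    )


def solve_fba(
    net: MetabolicNetwork,
    constraints: Optional[ConstraintSet] = None,
    objective: Optional[str] = None,
    parsimonious: bool = True,
) -> FluxSolution:
    """Maximize the objective reaction subject to S·v = 0 and bounds.

    With ``parsimonious`` (default) a second LP minimizes total absolute flux
    at the fixed optimal objective, making the reported per-reaction fluxes
    unique enough for condition comparisons.
    """
    S = net.stoichiometry_matrix()
    if constraints is not None:
        lb, ub = constraints.apply(net)
    else:
        lb, ub = net.bounds()
    if objective is not None:
        c = np.zeros(len(net.reactions))
        c[net.reaction_index(objective)] = 1.0
    else:
        c = net.objective_vector()
    b = np.zeros(S.shape[0])

    res = _linprog_solve(-c, S, b, lb, ub)
    if res.status == 2:
        return FluxSolution(None, None, "infeasible")
    if res.status == 3:
        return FluxSolution(None, None, "unbounded")
    if not res.success:
        return FluxSolution(None, None, f"solver_failure_{res.status}")
    z_opt = float(-res.fun)
    v = res.x

    if parsimonious:
        n = len(net.reactions)
        # variables [v, t], minimize sum t, with t >= |v| and c.v >= z_opt - tol
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        A_eq2 = np.hstack([S, np.zeros_like(S)])
        eye = np.eye(n)
        A_ub2 = np.vstack([
            np.hstack([eye, -eye]),
            np.hstack([-eye, -eye]),
            np.concatenate([-c, np.zeros(n)])[None, :],
        ])
        b_ub2 = np.concatenate([np.zeros(2 * n), [-(z_opt - 1e-9)]])
        t_hi = np.maximum(np.abs(lb), np.abs(ub))
        res2 = _linprog_solve(
            c2, A_eq2, b, np.concatenate([lb, np.zeros(n)]),
            np.concatenate([ub, t_hi]), A_ub2, b_ub2,
        )
        if res2.success:
            v = res2.x[:n]

    fluxes = pd.Series(v, index=net.reaction_ids)
    return FluxSolution(fluxes=fluxes, objective_value=z_opt, status="optimal")


def _resample_constraints(
    base: ConstraintSet, net: MetabolicNetwork, rng: np.random.Generator,
    k_sd: float,
) -> ConstraintSet:
    """Redraw each measured rate from a truncated normal and rebuild bounds."""
    new_bounds: Dict[str, Tuple[float, float]] = {}
    o2_bounds = base.o2_bounds
    o2_ids = set(net.tagged("O2_exchange"))
    for rxn_id, (rate, sd) in base.provenance.items():
        rxn = net.reaction(rxn_id)
        if sd > 0:
            a = (rxn.lb - rate) / sd
            bsd = (rxn.ub - rate) / sd
            draw = float(truncnorm.rvs(a, bsd, loc=rate, scale=sd, random_state=rng))
        else:
            draw = rate
        lo, hi = _clip_interval(draw - k_sd * sd, draw + k_sd * sd, rxn.lb, rxn.ub)
        if rxn_id in o2_ids:
            o2_bounds = (lo, hi)
        else:
            new_bounds[rxn_id] = (lo, hi)
    return ConstraintSet(
        exchange_bounds=new_bounds,
        omitted_metabolites=base.omitted_metabolites,
        growth_bounds=base.growth_bounds,
        o2_bounds=o2_bounds,
        provenance=base.provenance,
    )


def ensemble_fba(
    net: MetabolicNetwork,
    constraints: ConstraintSet,
    n: int = 1000,
    seed: int = 0,
    k_sd: float = 1.0,
    condition: str = "",
    parsimonious: bool = True,
) -> FluxEnsemble:
    """Constraint-resampling ensemble of n FBA solves.

    Each run draws every measured rate from a truncated normal centered on the
    measurement (SD = measurement SD, truncated to the default network bounds),
    rebuilds interval bounds of half-width ``k_sd``·SD around the draw, and
    solves. Optimal rows are collected; infeasible draws are counted. Fixed
    seed -> bit-identical ensemble.
    """
    rng = np.random.default_rng(seed)
    rows = []
    bounds_used = []
    infeasible = 0
    for _ in range(n):
        drawn = _resample_constraints(constraints, net, rng, k_sd)
        sol = solve_fba(net, drawn, parsimonious=parsimonious)
        if sol.status == "optimal":
            rows.append(sol.fluxes)
            bounds_used.append(drawn.apply(net))
        else:
            infeasible += 1
    if infeasible > n // 2:
        tightest = sorted(
            constraints.provenance.items(), key=lambda kv: abs(kv[1][1])
        )[:5]
        logger.warning(
            "ensemble %r: %d/%d draws infeasible; tightest constraints: %s",
            condition, infeasible, n,
            ", ".join(f"{k} (sd={sd:g})" for k, (_, sd) in tightest),
        )
    fluxes = (
        pd.DataFrame(rows).reset_index(drop=True)
        if rows
        else pd.DataFrame(columns=net.reaction_ids)
    )
    return FluxEnsemble(
        condition=condition,
        n_runs=n,
        fluxes=fluxes,
        seed=seed,
        infeasible_count=infeasible,
        network_reactions=tuple(net.reaction_ids),
        drawn_bounds=tuple(bounds_used),
    )


def compare_conditions(
    ensemble_a: FluxEnsemble,
    ensemble_b: FluxEnsemble,
    net: MetabolicNetwork,
    reactions: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-reaction ensemble means/SDs for two conditions plus direction.

    Defaults to the tagged bioenergetic subset. ``direction`` is the sign of
    mean(A) - mean(B) ("higher_in_a" / "higher_in_b" / "equal").
    """
    if ensemble_a.network_reactions != ensemble_b.network_reactions:
        raise NetworkError("ensembles come from different networks")
    if reactions is None:
        reactions = [rid for tag in BIOENERGETIC_TAGS for rid in net.tagged(tag)]
        seen = set()
        reactions = [r for r in reactions if not (r in seen or seen.add(r))]
    rows = []
    for rxn_id in reactions:
        a = ensemble_a.fluxes[rxn_id].to_numpy(dtype=float)
        b = ensemble_b.fluxes[rxn_id].to_numpy(dtype=float)
        mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
        diff = mean_a - mean_b
        rows.append(
            {
                "reaction": rxn_id,
                f"mean_{ensemble_a.condition or 'a'}": mean_a,
                f"sd_{ensemble_a.condition or 'a'}": float(np.std(a, ddof=1)) if len(a) > 1 else 0.0,
                f"mean_{ensemble_b.condition or 'b'}": mean_b,
                f"sd_{ensemble_b.condition or 'b'}": float(np.std(b, ddof=1)) if len(b) > 1 else 0.0,
                "difference": diff,
                "direction": (
                    "higher_in_" + (ensemble_a.condition or "a") if diff > 0
                    else "higher_in_" + (ensemble_b.condition or "b") if diff < 0
                    else "equal"
                ),
            }
        )
    return pd.DataFrame(rows).set_index("reaction")
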