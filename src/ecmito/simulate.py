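"""LP solving and simulation protocols: chemostat, batch, GAEC and sigma fits.

All protocols reduce to linear programs over the (possibly enzyme-
constrained) stoichiometric model; the LPs are solved with COBRApy/GLPK.
The chemostat protocol mirrors continuous-culture physiology: fix the
dilution rate, minimize substrate uptake, then minimize total enzyme usage
(parsimonious step).  Batch growth is a binary search for the maximum
feasible growth rate.  The growth-associated energy cost (GAEC) splits into
a polymerization component computed from the biomass composition and a
residual component fitted to chemostat exchange fluxes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import cobra
import numpy as np
import pandas as pd
from scipy import optimize

from .ec_constraints import ANN_EC_APPLIED, POOL_SOURCE_ID, rescale_for_growth_rate, set_sigma
from .model_core import Model, ModelError

logger = logging.getLogger(__name__)

cobra_config = cobra.Configuration()
cobra_config.solver = "glpk"

FEASIBILITY_TOL = 1e-9


class SimulationError(ModelError):
    """A simulation protocol could not complete."""


@dataclass
class SimulationResult:
    mu: float = 0.0
    fluxes: dict = field(default_factory=dict)
    enzyme_usage: dict = field(default_factory=dict)
    objective_value: float = 0.0
    status: str = "optimal"
    reports: dict = field(default_factory=dict)

    def exchange_summary(self, model: Model) -> dict:
        out = {}
        for rxn in model.reactions.values():
            if rxn.is_exchange:
                out[rxn.id] = self.fluxes.get(rxn.id, 0.0)
        return out


@dataclass
class ExchangeDataset:
    """Chemostat exchange fluxes per dilution rate (mmol/gDW/h; mu in 1/h)."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("mu", "glucose", "o2", "co2", "ethanol", "acetate", "glycerol", "pyruvate")

    def __post_init__(self) -> None:
        if len(self.rows):
            missing = set(self.COLUMNS) - set(self.rows.columns)
            if missing:
                raise ValueError(f"dataset missing columns {sorted(missing)}")
            mus = self.rows["mu"].to_numpy()
            if not np.all(np.diff(mus) > 0):
                raise ValueError("dilution rates must be strictly increasing")


# ---------------------------------------------------------------------------
# FBA core
# ---------------------------------------------------------------------------

def to_cobra(model: Model) -> cobra.Model:
    cm = cobra.Model(model.id)
    for comp in model.compartments.values():
        cm.compartments[comp.id] = comp.name or comp.id
    mets = {}
    for met in model.metabolites.values():
        m = cobra.Metabolite(met.id, name=met.name, compartment=met.compartment)
        mets[met.id] = m
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for rxn in model.reactions.values():
        r = cobra.Reaction(rxn.id, name=rxn.name,
                           lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound)
        rxns.append(r)
    cm.add_reactions(rxns)
    for rxn in model.reactions.values():
        cm.reactions.get_by_id(rxn.id).add_metabolites(
            {mets[mid]: coef for mid, coef in rxn.stoichiometry.items()}
        )
    # enzyme-coupling coefficients span ~1e-7..1e3; tight tolerances keep the
    # simplex honest on this badly scaled problem
    cm.solver.configuration.tolerances.feasibility = FEASIBILITY_TOL
    try:
        cm.solver.configuration.tolerances.optimality = FEASIBILITY_TOL
    except AttributeError:
        pass
    return cm


def solve(model: Model, objective: str, sense: str = "max") -> SimulationResult:
    """Plain FBA: optimize one reaction's flux subject to steady state."""
    if objective not in model.reactions:
        raise SimulationError(f"unknown objective reaction {objective!r}")
    cm = to_cobra(model)
    cm.objective = cm.reactions.get_by_id(objective)
    cm.objective_direction = sense
    cm.slim_optimize(error_value=float("nan"))
    status = cm.solver.status
    if status != "optimal":
        return SimulationResult(status=status)
    sol = cm.optimize()
    fluxes = {rid: float(sol.fluxes[rid]) for rid in sol.fluxes.index}
    usage = {
        rxn.annotations["enzyme_draw"]: fluxes.get(rxn.id, 0.0)
        for rxn in model.reactions.values()
        if "enzyme_draw" in rxn.annotations
    }
    biomass = model.biomass_reaction
    mu = fluxes.get(biomass.id, 0.0) if biomass is not None else 0.0
    return SimulationResult(
        mu=mu,
        fluxes=fluxes,
        enzyme_usage=usage,
        objective_value=float(sol.objective_value),
        status="optimal",
    )


def _solve_cobra(cm: cobra.Model, objective: str, sense: str):
    cm.objective = cm.reactions.get_by_id(objective)
    cm.objective_direction = sense
    return cm.optimize()


# ---------------------------------------------------------------------------
# chemostat protocol
# ---------------------------------------------------------------------------

GLUCOSE_EXCHANGE = "EX_glc"
ETHANOL_EXCHANGE = "EX_etoh"
#: dataset column -> exchange reaction, sign +1 if the column reports secretion
DATASET_EXCHANGES = {
    "glucose": (GLUCOSE_EXCHANGE, -1),
    "o2": ("EX_o2", -1),
    "co2": ("EX_co2", 1),
    "ethanol": (ETHANOL_EXCHANGE, 1),
    "acetate": ("EX_ac", 1),
    "glycerol": ("EX_glyc", 1),
    "pyruvate": ("EX_pyr", 1),
}


def simulate_chemostat(
    model: Model,
    mu: float,
    dataset_row: Optional[Mapping[str, float]] = None,
    carbon_exchange: str = GLUCOSE_EXCHANGE,
    scaled: bool = True,
) -> SimulationResult:
    """Chemostat steady state at dilution rate ``mu``.

    Protocol: open substrate uptake on minimal medium, fix the growth rate,
    apply the growth-rate scaling of the enzyme constraints, minimize the
    substrate uptake rate, fix it, then minimize total enzyme usage (the
    parsimonious step, as pool-source flux = total enzyme mass).  When a
    dataset row is given, byproduct secretion (acetate, pyruvate) is capped
    at the measured values.
    """
    work = model.copy()
    biomass = work.biomass_reaction
    if biomass is None:
        raise SimulationError("model has no biomass reaction")
    if mu > 0 and work.annotations.get(ANN_EC_APPLIED) and scaled:
        work = rescale_for_growth_rate(work, mu)
    biomass = work.biomass_reaction
    biomass.lower_bound = biomass.upper_bound = mu
    for other in (GLUCOSE_EXCHANGE, ETHANOL_EXCHANGE):
        if other in work.reactions and other != carbon_exchange:
            work.reactions[other].lower_bound = 0.0
    sub = work.reactions[carbon_exchange]
    sub.lower_bound, sub.upper_bound = -1000.0, 0.0
    if dataset_row is not None:
        for col in ("acetate", "pyruvate"):
            if col in dataset_row and not math.isnan(dataset_row[col]):
                rid, _ = DATASET_EXCHANGES[col]
                if rid in work.reactions:
                    work.reactions[rid].upper_bound = float(dataset_row[col])

    cm = to_cobra(work)
    sol = _solve_cobra(cm, carbon_exchange, "max")  # uptake is negative flux
    if sol.status != "optimal":
        raise SimulationError(
            f"chemostat infeasible at mu={mu}; if mu exceeds mu_max use the batch protocol"
        )
    uptake_flux = float(sol.fluxes[carbon_exchange])
    rxn = cm.reactions.get_by_id(carbon_exchange)
    rxn.lower_bound = rxn.upper_bound = uptake_flux
    if work.annotations.get(ANN_EC_APPLIED) and POOL_SOURCE_ID in work.reactions:
        sol = _solve_cobra(cm, POOL_SOURCE_ID, "min")
        if sol.status != "optimal":
            raise SimulationError("parsimonious enzyme-usage step failed")

    fluxes = {r.id: float(sol.fluxes[r.id]) for r in cm.reactions}
    usage = {
        rxn2.annotations["enzyme_draw"]: fluxes.get(rxn2.id, 0.0)
        for rxn2 in work.reactions.values()
        if "enzyme_draw" in rxn2.annotations
    }
    result = SimulationResult(
        mu=mu, fluxes=fluxes, enzyme_usage=usage,
        objective_value=fluxes.get(POOL_SOURCE_ID, uptake_flux), status="optimal",
    )
    result.reports["uptake"] = -uptake_flux
    return result


# ---------------------------------------------------------------------------
# batch protocol
# ---------------------------------------------------------------------------

def simulate_batch_mu_max(
    model: Model,
    carbon_source: str = "glucose",
    tolerance: float = 1e-4,
    mu_bracket: tuple = (0.0, 1.0),
):
    """Binary search for the maximum feasible growth rate on excess substrate.

    Feasibility at each candidate mu is checked with the plain (unscaled)
    enzyme-constraint formulation, which is equivalent at fixed mu; at the
    found mu_max the substrate uptake is minimized and fixed, and total
    enzyme usage minimized.  Returns ``(mu_max, SimulationResult)``.
    """
    exchange = {"glucose": GLUCOSE_EXCHANGE, "ethanol": ETHANOL_EXCHANGE}[carbon_source]
    work = model.copy()
    for other in (GLUCOSE_EXCHANGE, ETHANOL_EXCHANGE):
        if other in work.reactions and other != exchange:
            work.reactions[other].lower_bound = 0.0
    sub = work.reactions[exchange]
    sub.lower_bound, sub.upper_bound = -1000.0, 0.0
    biomass = work.biomass_reaction
    if biomass is None:
        raise SimulationError("model has no biomass reaction")

    cm = to_cobra(work)
    bio = cm.reactions.get_by_id(biomass.id)

    def feasible(mu: float) -> bool:
        bio.bounds = (mu, mu)
        sol = _solve_cobra(cm, exchange, "max")
        return sol.status == "optimal"

    lo, hi = mu_bracket
    if not feasible(lo + 1e-9):
        raise SimulationError("infeasible even at mu -> 0+; check the medium")
    if feasible(hi):
        logger.warning("mu_max at or above bracket top %.3g", hi)
        lo = hi
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    mu_max = lo
    result = simulate_chemostat(model, mu_max, carbon_exchange=exchange)
    return mu_max, result


# ---------------------------------------------------------------------------
# GAEC and sigma fitting
# ---------------------------------------------------------------------------

def set_biomass_gaec(model: Model, gaec: float) -> Model:
    """Set the fitted (non-polymerization) ATP component of the biomass reaction."""
    if gaec < 0:
        raise ValueError("GAEC must be non-negative")
    model = model.copy()
    biomass = model.biomass_reaction
    if biomass is None:
        raise SimulationError("model has no biomass reaction")
    for mid, sign in (("atp_c", -1), ("h2o_c", -1), ("adp_c", 1), ("h2po4_c", 1)):
        biomass.stoichiometry[mid] = sign * gaec
    model.annotations["gaec_fitted"] = gaec
    return model


def polymerization_gaec(model: Model) -> float:
    """ATP per gDW spent polymerizing macromolecules, from the composition.

    Sums, over every macromolecular pool consumed by biomass, the pool's
    biomass coefficient times the ATP coefficient of its synthesis reaction.
    """
    biomass = model.biomass_reaction
    if biomass is None:
        raise SimulationError("model has no biomass reaction")
    pools = biomass.annotations.get("macromolecule_pools")
    if pools is None:
        pools = [mid for mid, c in biomass.stoichiometry.items() if c < 0 and mid.endswith("_pool_c")]
    total = 0.0
    for mid in pools:
        coef = biomass.stoichiometry.get(mid, 0.0)
        if coef >= 0:
            continue
        makers = [
            r for r in model.reactions.values()
            if r.stoichiometry.get(mid, 0) > 0 and not r.is_exchange and not r.is_biomass
        ]
        for maker in makers:
            atp = -maker.stoichiometry.get("atp_c", 0.0) - maker.stoichiometry.get("atp_mm", 0.0)
            if atp > 0:
                total += (-coef) * atp / maker.stoichiometry[mid]
    return total


def _exchange_error(model: Model, dataset: ExchangeDataset,
                    columns: Sequence[str] = ("glucose", "o2", "co2")) -> float:
    err = 0.0
    for _, row in dataset.rows.iterrows():
        try:
            result = simulate_chemostat(model, float(row["mu"]))
        except SimulationError:
            return 1e6
        for col in columns:
            rid, sign = DATASET_EXCHANGES[col]
            obs = float(row[col])
            pred = sign * result.fluxes.get(rid, 0.0)
            if abs(obs) > 1e-9:
                err += ((pred - obs) / obs) ** 2
            else:
                err += pred ** 2
    return err


def fit_gaec(
    model: Model,
    dataset: ExchangeDataset,
    bounds: tuple = (0.0, 60.0),
    tolerance: float = 1e-3,
):
    """Estimate the GAEC from chemostat exchange data.

    Returns ``(polymerization_component, fitted_component)`` in mmol
    ATP/gDW.  The fitted component minimizes the summed squared relative
    error of the glucose, O2 and CO2 exchange fluxes across the dataset's
    dilution rates (1-D bounded search).
    """
    if len(dataset.rows) < 2:
        raise SimulationError("GAEC fitting needs at least 2 dilution rates")

    def objective(g: float) -> float:
        return _exchange_error(set_biomass_gaec(model, g), dataset)

    res = optimize.minimize_scalar(
        objective, bounds=bounds, method="bounded", options={"xatol": tolerance}
    )
    if not res.success or objective(res.x) >= 1e6:
        raise SimulationError("no feasible GAEC in the search interval")
    return polymerization_gaec(model), float(res.x)


def fit_sigma(
    model: Model,
    dataset: ExchangeDataset,
    bounds: tuple = (0.05, 1.0),
    tolerance: float = 1e-4,
) -> float:
    """Fit the average enzyme saturation sigma to chemostat exchange data.

    Sigma only binds where the enzyme pool is limiting, so the error is
    evaluated over the dataset rows at and above the critical dilution rate
    (first row with nonzero fermentation byproducts; all rows if none).
    Returns the boundary value with a warning when the optimum is not
    bracketed.
    """
    if not model.annotations.get("enzyme_pool"):
        raise SimulationError("pool constraint not applied; cannot fit sigma")
    rows = dataset.rows
    overflow = rows[rows["ethanol"] > 1e-6]
    sub = ExchangeDataset(rows if overflow.empty else rows[rows["mu"] >= overflow["mu"].min()].reset_index(drop=True))

    def objective(sigma: float) -> float:
        return _exchange_error(set_sigma(model, sigma), sub,
                               columns=("glucose", "o2", "co2", "ethanol"))

    res = optimize.minimize_scalar(
        objective, bounds=bounds, method="bounded", options={"xatol": tolerance}
    )
    sigma = float(res.x)
    for boundary in bounds:
        if abs(sigma - boundary) < 5 * tolerance and objective(boundary) <= res.fun + 1e-12:
            logger.warning("sigma optimum at search boundary %.3g", boundary)
            return float(boundary)
    return sigma
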