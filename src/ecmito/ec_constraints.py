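"""GECKO-style enzyme-capacity constraints with a shared protein pool.

Each catalyzed reaction j with enzyme i is coupled as v_j <= kcat_ij * e_i by
letting the reaction consume 1/kcat_ij units of the enzyme's species per unit
flux, while a draw reaction supplies the enzyme from an aggregated pool
pseudo-metabolite at a cost of MW_i grams per mmol.  The pool source is
capped at sigma * f * Ptot (saturation x modeled mass fraction x total
protein content, g/gDW), so the summed mass of all enzyme usage cannot
exceed the cell's protein budget.

The growth-rate-scaled variant multiplies each usage coefficient by mu and
divides the pool-draw coefficient by mu; at fixed mu this is unit
bookkeeping and leaves the optimal flux distribution unchanged (the module's
central correctness property).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Mapping, Optional

from .model_core import Metabolite, Model, ModelError, Reaction

logger = logging.getLogger(__name__)

POOL_METABOLITE_ID = "enzyme_pool"
POOL_SOURCE_ID = "PROT_POOL_SOURCE"
ANN_EC_APPLIED = "ec_applied"
ANN_MU_SCALED = "mu_scaled"
ANN_COUPLING = "enzyme_coupling"  # reaction annotation: {species: kcat}


class ECParameterError(ModelError):
    """A kcat or pool parameter is out of range or missing."""


@dataclass
class EnzymePool:
    """Pool parameters: saturation sigma, modeled fraction f, content Ptot."""

    sigma: float = 0.53
    f: float = 0.446
    ptot: float = 0.46

    def __post_init__(self) -> None:
        for name in ("sigma", "f", "ptot"):
            value = getattr(self, name)
            if not (0 < value <= 1):
                raise ECParameterError(f"{name} must be in (0, 1], got {value}")

    @property
    def bound(self) -> float:
        """Pool mass bound sigma*f*Ptot in g enzyme/gDW."""
        return self.sigma * self.f * self.ptot


def usage_species_id(protein_id: str) -> str:
    return f"prot_{protein_id}_c"


def draw_reaction_id(protein_id: str) -> str:
    return f"DRAW_{protein_id}"


def apply_enzyme_constraints(
    model: Model,
    kcats: Optional[Mapping[tuple, float]] = None,
    abundance_caps: bool = False,
) -> Model:
    """Couple every enzyme-annotated reaction to enzyme usage variables.

    ``kcats`` maps (protein_id, reaction_id) to a turnover in 1/h and
    overrides the kcat stored on the reaction; reactions whose enzymes lack
    any kcat fall back to the median of all supplied values (logged).  Each
    enzyme's draw reaction is the usage variable e_i; summed consumption over
    the enzyme's reactions is capped by it, isoenzymes (duplicate reactions)
    draw independently, and complex subunits listed on one reaction are all
    engaged stoichiometrically.  With ``abundance_caps`` the draw upper bound
    is the measured concentration [E_i] where available.
    """
    kcats = dict(kcats or {})
    model = model.copy()
    if model.annotations.get(ANN_EC_APPLIED):
        return model
    species_map = model.annotations.setdefault("enzyme_species", {})

    all_kcats = [k for _, k in kcats.items()] + [
        k for r in model.reactions.values() for _, k in r.enzymes
    ]
    for k in all_kcats:
        if k <= 0:
            raise ECParameterError(f"non-positive kcat {k}")
    median_kcat = statistics.median(all_kcats) if all_kcats else None

    if "pseudo" not in model.compartments:
        from .model_core import Compartment

        model.add_compartment(Compartment("pseudo", "pseudo entities", "pseudo"))

    # reversible catalyzed reactions are split into irreversible arms so each
    # direction consumes (never produces) enzyme capacity
    for rxn in [r for r in model.reactions.values() if r.enzymes and r.lower_bound < 0]:
        rev = rxn.copy()
        rev.id = rxn.id + "_REV"
        rev.name = (rxn.name or rxn.id) + " (reverse)"
        rev.stoichiometry = {mid: -coef for mid, coef in rxn.stoichiometry.items()}
        rev.lower_bound, rev.upper_bound = 0.0, -rxn.lower_bound
        rxn.lower_bound = 0.0
        model.add_reaction(rev)

    catalyzed = [r for r in model.reactions.values() if r.enzymes]
    for rxn in catalyzed:
        coupling = {}
        for pid, kcat in rxn.enzymes:
            if pid not in model.proteins:
                raise ECParameterError(f"reaction {rxn.id}: unknown protein {pid}")
            kcat_eff = kcats.get((pid, rxn.id), kcat)
            if kcat_eff is None or kcat_eff <= 0:
                if median_kcat is None:
                    raise ECParameterError(f"no kcat available for ({pid}, {rxn.id})")
                logger.info(
                    "no kcat for (%s, %s); falling back to median %.3g", pid, rxn.id, median_kcat
                )
                kcat_eff = median_kcat
            species = species_map.get(pid)
            if species is None:
                species = usage_species_id(pid)
                species_map[pid] = species
            if species not in model.metabolites:
                model.add_metabolite(
                    Metabolite(species, name=f"{pid} usage", compartment="pseudo",
                               charge=0, is_pseudo=True)
                )
            rxn.stoichiometry[species] = rxn.stoichiometry.get(species, 0.0) - 1.0 / kcat_eff
            coupling[species] = kcat_eff
        rxn.annotations[ANN_COUPLING] = coupling

    # one draw (usage) variable per protein that appears in any coupling,
    # producing the *first* species of its synthesis/import/maturation chain
    needed = set()
    for rxn in catalyzed:
        for pid, _ in rxn.enzymes:
            needed.add(pid)
    for pid in sorted(needed):
        first_species = usage_species_id(pid)
        if first_species not in model.metabolites:
            model.add_metabolite(
                Metabolite(first_species, name=f"{pid} (cytosolic)", compartment="pseudo",
                           charge=0, is_pseudo=True)
            )
        rid = draw_reaction_id(pid)
        if rid in model.reactions:
            continue
        ub = 1000.0
        if abundance_caps and model.proteins[pid].abundance is not None:
            ub = model.proteins[pid].abundance
        model.add_reaction(
            Reaction(
                id=rid,
                name=f"usage of {pid}",
                stoichiometry={first_species: 1.0},
                lower_bound=0.0,
                upper_bound=ub,
                subsystem="enzyme_usage",
                annotations={"enzyme_draw": pid},
            )
        )
    model.annotations[ANN_EC_APPLIED] = True
    return model


def apply_pool_constraint(model: Model, pool: EnzymePool = None) -> Model:
    """Add the shared enzyme pool: sum_i MW_i * e_i <= sigma*f*Ptot.

    Implemented as a pool pseudo-metabolite consumed MW_i per unit draw flux
    and a source reaction capped at the pool bound.
    """
    pool = pool or EnzymePool()
    model = model.copy()
    if not model.annotations.get(ANN_EC_APPLIED):
        raise ECParameterError("apply enzyme constraints before the pool constraint")
    missing_mw = [
        r.annotations["enzyme_draw"]
        for r in model.reactions.values()
        if "enzyme_draw" in r.annotations
        and model.proteins[r.annotations["enzyme_draw"]].mw <= 0
    ]
    if missing_mw:
        raise ECParameterError(f"missing molecular weights for: {sorted(missing_mw)}")

    if POOL_METABOLITE_ID not in model.metabolites:
        model.add_metabolite(
            Metabolite(POOL_METABOLITE_ID, name="aggregated enzyme pool",
                       compartment="pseudo", charge=0, is_pseudo=True)
        )
    for rxn in model.reactions.values():
        pid = rxn.annotations.get("enzyme_draw")
        if pid is not None:
            rxn.stoichiometry[POOL_METABOLITE_ID] = -model.proteins[pid].mw
    if POOL_SOURCE_ID not in model.reactions:
        model.add_reaction(
            Reaction(
                id=POOL_SOURCE_ID,
                name="protein pool source",
                stoichiometry={POOL_METABOLITE_ID: 1.0},
                lower_bound=0.0,
                upper_bound=pool.bound,
                subsystem="enzyme_usage",
            )
        )
    else:
        model.reactions[POOL_SOURCE_ID].upper_bound = pool.bound
    model.annotations["enzyme_pool"] = {
        "sigma": pool.sigma, "f": pool.f, "ptot": pool.ptot, "bound": pool.bound,
    }
    return model


def set_sigma(model: Model, sigma: float) -> Model:
    """Re-cap the pool source for a new saturation value (f, Ptot unchanged)."""
    params = model.annotations.get("enzyme_pool")
    if params is None:
        raise ECParameterError("pool constraint not applied")
    pool = EnzymePool(sigma=sigma, f=params["f"], ptot=params["ptot"])
    model = model.copy()
    model.reactions[POOL_SOURCE_ID].upper_bound = pool.bound
    model.annotations["enzyme_pool"] = {
        "sigma": pool.sigma, "f": pool.f, "ptot": pool.ptot, "bound": pool.bound,
    }
    return model


def rescale_for_growth_rate(model: Model, mu: float) -> Model:
    """Apply the growth-rate scaling of usage and pool-draw coefficients.

    Multiplies each enzyme-usage coefficient by mu (usage per unit flux
    becomes mu/kcat) and divides the pool coefficient of every draw reaction
    by mu.  The optimal flux distribution at fixed mu is identical to the
    unscaled formulation; the transformation only changes the unit the usage
    variables are expressed in.
    """
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    model = model.copy()
    if not model.annotations.get(ANN_EC_APPLIED):
        raise ECParameterError("enzyme constraints not applied; nothing to rescale")
    if model.annotations.get(ANN_MU_SCALED):
        raise ECParameterError("model already growth-rate scaled")
    for rxn in model.reactions.values():
        coupling = rxn.annotations.get(ANN_COUPLING) or {}
        for species in coupling:
            rxn.stoichiometry[species] *= mu
        if "enzyme_draw" in rxn.annotations:
            if POOL_METABOLITE_ID in rxn.stoichiometry:
                rxn.stoichiometry[POOL_METABOLITE_ID] /= mu
            continue
        # maturation-chain steps (import, cofactor incorporation) move protein
        # species 1:1; scaling those coefficients with mu keeps the chain's
        # per-enzyme costs identical to the unscaled formulation, making the
        # transformation pure unit bookkeeping
        for mid in rxn.stoichiometry:
            if mid.startswith("prot_") and mid not in coupling:
                rxn.stoichiometry[mid] *= mu
    model.annotations[ANN_MU_SCALED] = mu
    return model
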