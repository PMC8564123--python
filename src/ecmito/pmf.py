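"""Proton-motive-force (PMF) coupling of inner-membrane charge translocation.

The electrochemical gradient across the inner mitochondrial membrane is
represented by a pseudo-metabolite.  Reactions that move net charge across the
membrane dissipate (or charge) the membrane-potential component and are
coupled at ``delta_psi_fraction`` (default 0.9) PMF per elementary charge;
electroneutral but proton-coupled carriers dissipate the pH component at
``delta_ph_fraction`` (default 0.1) PMF per proton.  The respiratory-chain
complexes *produce* PMF, one per proton translocated (both components), and
the ATP synthase consumes ``synthase_pmf_per_atp`` (default 3) per ATP.

With those defaults, delivering one cytosolic ATP costs 3 (synthase) + 0.9
(ADP/ATP translocase) + 0.1 (phosphate carrier) = 4 PMF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .model_core import Model, ModelError, Reaction, Metabolite, Compartment

logger = logging.getLogger(__name__)

PMF_METABOLITE_ID = "pmf"
PMF_SINK_ID = "PMF_SINK"

# reaction annotation keys understood by the coupler
ANN_PROTON_PUMP = "etc_pmf_per_unit"   # chain complexes: PMF produced per unit flux
ANN_SYNTHASE = "atp_synthase"          # boolean tag on the ATP synthase
ANN_COUPLED = "pmf_coupling"           # record of the applied PMF coefficient

_MATRIX = "mito_matrix"
# species sitting in the inner membrane itself (the quinone pool) are reachable
# from both faces and do not constitute a crossing
_OUTSIDE = {"mito_intermembrane_space", "cytosol"}


class MissingChargeError(ModelError):
    """A membrane-spanning reaction contains a metabolite without a charge."""


class PMFMisuseError(ModelError):
    """A PMF operation was applied to an unsuitable reaction or model."""


@dataclass
class PMFSpec:
    """Split of the PMF into membrane potential and pH components.

    ``delta_psi_fraction`` + ``delta_ph_fraction`` must equal 1; the defaults
    (0.9/0.1) are the experimentally measured average contributions of the two
    components in yeast mitochondria.
    """

    delta_psi_fraction: float = 0.9
    delta_ph_fraction: float = 0.1
    synthase_pmf_per_atp: float = 3.0
    pmf_metabolite_id: str = PMF_METABOLITE_ID

    def __post_init__(self) -> None:
        if not math.isclose(self.delta_psi_fraction + self.delta_ph_fraction, 1.0):
            raise ValueError("delta_psi_fraction + delta_ph_fraction must equal 1")
        if min(self.delta_psi_fraction, self.delta_ph_fraction, self.synthase_pmf_per_atp) <= 0:
            raise ValueError("all PMFSpec fields must be positive")


@dataclass
class TranslocationProfile:
    """Net charge/proton movement of one reaction across the inner membrane.

    ``net_charge_moved`` is per unit forward flux, positive for charge leaving
    the matrix.  ``protons_moved`` is positive for protons entering the matrix
    (the gradient-dissipating direction).
    """

    reaction_id: str
    net_charge_moved: float = 0.0
    protons_moved: float = 0.0
    classification: str = "neutral"


def _is_proton(met: Metabolite) -> bool:
    return (met.formula == "H" and (met.charge or 0) == 1)


def classify_translocation(reaction: Reaction, model: Model) -> TranslocationProfile:
    """Classify a reaction's effect on the inner-membrane gradient.

    Reactions not spanning the matrix and the intermembrane side are neutral.
    Membrane-spanning reactions must carry charges on every participating
    metabolite.
    """
    kinds = {model.compartment_kind(mid) for mid in reaction.stoichiometry
             if not model.metabolites[mid].is_pseudo}
    if _MATRIX not in kinds or not (kinds & _OUTSIDE):
        return TranslocationProfile(reaction.id)

    net_out = 0.0
    protons_in = 0.0
    for mid, coef in reaction.stoichiometry.items():
        met = model.metabolites[mid]
        if met.is_pseudo:
            continue
        if met.charge is None:
            raise MissingChargeError(
                f"metabolite {mid} in membrane-spanning reaction {reaction.id} has no charge"
            )
        if model.compartment_kind(mid) == _MATRIX:
            # production in the matrix (+coef) means the species entered it
            net_out += -coef * met.charge
            if _is_proton(met):
                protons_in += coef
    # a proton crossing contributes to both terms; the charge term nets to zero
    # for electroneutral symports, leaving only the pH component.
    if abs(net_out) > 1e-9:
        cls = "charge_translocating"
    elif abs(protons_in) > 1e-9:
        cls = "proton_coupled_electroneutral"
    else:
        cls = "neutral"
    return TranslocationProfile(reaction.id, net_out, protons_in, cls)


def ensure_pmf_metabolite(model: Model, spec: PMFSpec) -> None:
    if spec.pmf_metabolite_id in model.metabolites:
        return
    if "pseudo" not in model.compartments:
        model.add_compartment(Compartment("pseudo", "pseudo entities", "pseudo"))
    model.add_metabolite(
        Metabolite(
            id=spec.pmf_metabolite_id,
            name="proton motive force",
            compartment="pseudo",
            charge=0,
            is_pseudo=True,
        )
    )


def pmf_coefficient(reaction: Reaction, model: Model, spec: PMFSpec) -> float:
    """Signed PMF coefficient for one reaction under the coupling rules.

    Order of precedence: explicit chain-complex proton count (produces PMF at
    1 per proton), ATP synthase tag (consumes ``synthase_pmf_per_atp`` per ATP
    produced), then the classification decision table.  A negative coefficient
    is consumption per unit forward flux.
    """
    if ANN_PROTON_PUMP in reaction.annotations:
        return float(reaction.annotations[ANN_PROTON_PUMP])
    if reaction.annotations.get(ANN_SYNTHASE):
        atp_coef = next(
            (coef for mid, coef in reaction.stoichiometry.items()
             if mid.startswith("atp_") and coef > 0),
            None,
        )
        if atp_coef is None:
            raise PMFMisuseError(f"synthase-tagged reaction {reaction.id} produces no ATP")
        return -spec.synthase_pmf_per_atp * atp_coef
    profile = classify_translocation(reaction, model)
    if profile.classification == "neutral":
        return 0.0
    # charge leaving the matrix charges the gradient (+); charge entering, and
    # protons entering, dissipate it (-)
    return (
        spec.delta_psi_fraction * profile.net_charge_moved
        - spec.delta_ph_fraction * profile.protons_moved
    )


def apply_pmf_coupling(
    model: Model,
    spec: PMFSpec = None,
    overrides: Optional[Mapping[str, float]] = None,
) -> Model:
    """Inject PMF stoichiometry into every charge/proton-translocating reaction.

    Idempotent: a previously applied coefficient (recorded in the reaction
    annotations) is recomputed from scratch, so re-application is a no-op.
    ``overrides`` maps reaction id to an explicit signed PMF coefficient and
    wins over every rule; overriding a non-membrane, non-tagged reaction is an
    error.
    """
    spec = spec or PMFSpec()
    overrides = dict(overrides or {})
    model = model.copy()
    ensure_pmf_metabolite(model, spec)
    pmf_id = spec.pmf_metabolite_id

    for rid, coef in overrides.items():
        if rid not in model.reactions:
            raise PMFMisuseError(f"override names unknown reaction {rid!r}")
        rxn = model.reactions[rid]
        tagged = ANN_PROTON_PUMP in rxn.annotations or rxn.annotations.get(ANN_SYNTHASE)
        if not tagged and classify_translocation(rxn, model).classification == "neutral":
            raise PMFMisuseError(
                f"override on non-membrane reaction {rid!r} (nothing to couple)"
            )

    for rxn in model.reactions.values():
        if rxn.id == PMF_SINK_ID or rxn.is_exchange:
            continue
        if ANN_COUPLED in rxn.annotations:
            rxn.stoichiometry.pop(pmf_id, None)
            del rxn.annotations[ANN_COUPLED]
        coef = overrides.get(rxn.id)
        if coef is None:
            coef = pmf_coefficient(rxn, model, spec)
        if coef != 0.0:
            rxn.stoichiometry[pmf_id] = coef
            rxn.annotations[ANN_COUPLED] = coef
    model.annotations["pmf_spec"] = {
        "delta_psi_fraction": spec.delta_psi_fraction,
        "delta_ph_fraction": spec.delta_ph_fraction,
        "synthase_pmf_per_atp": spec.synthase_pmf_per_atp,
        "pmf_metabolite_id": spec.pmf_metabolite_id,
    }
    return model


def add_pmf_sink(model: Model, spec: PMFSpec = None, upper_bound: float = 1000.0) -> Model:
    """Add the PMF sink (leak) reaction: free dissipation of the gradient.

    The sink enables adjusting the operational P/O ratio; with its bound at 0
    it is inert.  Adding it twice is a logged no-op.
    """
    spec = spec or PMFSpec()
    model = model.copy()
    if PMF_SINK_ID in model.reactions:
        logger.info("PMF sink already present; leaving model unchanged")
        return model
    if spec.pmf_metabolite_id not in model.metabolites:
        raise PMFMisuseError("model has no PMF metabolite; apply_pmf_coupling first")
    model.add_reaction(
        Reaction(
            id=PMF_SINK_ID,
            name="PMF sink (proton leak)",
            stoichiometry={spec.pmf_metabolite_id: -1.0},
            lower_bound=0.0,
            upper_bound=upper_bound,
            subsystem="pmf",
            annotations={"pmf_sink": True},
        )
    )
    return model


# ---------------------------------------------------------------------------
# P/O ratio and PMF accounting
# ---------------------------------------------------------------------------

ANN_ELECTRON_ENTRY = "electron_pair_entry"  # NADH dehydrogenases and SDH
ATP_DEMAND_ID = "ATP_DEMAND"

OXPHOS_DRAIN_IDS = ("ATPS", "ANT", "PIC")


def close_non_oxphos_pmf_drains(model: Model, keep=OXPHOS_DRAIN_IDS,
                                spec: PMFSpec = None) -> Model:
    """Zero the bounds of PMF consumers other than OXPHOS and the sink.

    Restricts PMF consumption to ATP synthesis and ATP/phosphate transport
    (plus the explicitly bounded sink), the configuration under which the
    theoretical maximum P/O is attained.
    """
    spec = spec or PMFSpec()
    model = model.copy()
    keep = set(keep) | {PMF_SINK_ID}
    for rxn in model.reactions.values():
        if rxn.id in keep or rxn.annotations.get(ANN_SYNTHASE):
            continue
        if rxn.stoichiometry.get(spec.pmf_metabolite_id, 0.0) < 0:
            rxn.lower_bound = rxn.upper_bound = 0.0
    return model


def compute_po_ratio(model: Model, substrate: str, uptake: float = 1.0):
    """Maximum ATP yield per electron pair at a fixed substrate uptake.

    Fixes the uptake of ``substrate`` (an exchange reaction id), maximizes an
    ATP-hydrolysis demand, and returns ``(p_o, result)`` where ``p_o`` is the
    ATP synthase flux divided by the summed flux through the electron-pair
    entry points (NADH dehydrogenases and succinate dehydrogenase, tagged with
    the ``electron_pair_entry`` annotation).
    """
    from .simulate import solve  # local import to avoid a cycle

    if uptake <= 0:
        raise ValueError("uptake must be positive (P/O undefined at zero uptake)")
    if substrate not in model.reactions:
        raise PMFMisuseError(f"unknown substrate exchange {substrate!r}")

    work = model.copy()
    for rxn in work.reactions.values():
        if rxn.is_exchange and rxn.id != substrate and rxn.lower_bound < 0:
            if not rxn.annotations.get("essential_exchange"):
                rxn.lower_bound = 0.0
    sub = work.reactions[substrate]
    sub.lower_bound = sub.upper_bound = -uptake
    bio = work.biomass_reaction
    if bio is not None:
        bio.lower_bound = bio.upper_bound = 0.0
    if "NGAM" in work.reactions:
        work.reactions["NGAM"].lower_bound = 0.0
    if ATP_DEMAND_ID not in work.reactions:
        needed = {"atp_c", "h2o_c", "adp_c", "h2po4_c"}
        if not needed <= set(work.metabolites):
            raise PMFMisuseError("cannot auto-add ATP demand: cytosolic ATP species missing")
        work.add_reaction(
            Reaction(
                id=ATP_DEMAND_ID,
                name="ATP hydrolysis demand",
                stoichiometry={"atp_c": -1, "h2o_c": -1, "adp_c": 1, "h2po4_c": 1},
                lower_bound=0.0,
                upper_bound=1000.0,
            )
        )
    else:
        work.reactions[ATP_DEMAND_ID].upper_bound = 1000.0

    result = solve(work, objective=ATP_DEMAND_ID, sense="max")
    if result.status != "optimal":
        raise PMFMisuseError(f"P/O computation infeasible at uptake {uptake} ({result.status})")

    synthase_flux = sum(
        result.fluxes.get(r.id, 0.0)
        for r in work.reactions.values()
        if r.annotations.get(ANN_SYNTHASE)
    )
    pair_flux = sum(
        result.fluxes.get(r.id, 0.0)
        for r in work.reactions.values()
        if r.annotations.get(ANN_ELECTRON_ENTRY)
    )
    if pair_flux <= 1e-9:
        raise PMFMisuseError("no electron pairs entered the chain; P/O undefined")
    po = synthase_flux / pair_flux
    result.reports["p_o"] = po
    result.reports["synthase_flux"] = synthase_flux
    result.reports["electron_pair_flux"] = pair_flux
    return po, result


def pmf_accounting(result, model: Model, spec: PMFSpec = None):
    """Partition PMF consumption of a solution into consumer categories.

    Returns a :class:`pandas.DataFrame` with columns ``category``, ``pmf_flux``
    and ``fraction`` over the categories {atp_synthesis, transport, sink,
    other}; fractions sum to 1 and total consumption equals total production
    (the pseudo-metabolite is strictly balanced at steady state).
    """
    import pandas as pd

    spec = spec or PMFSpec()
    pmf_id = spec.pmf_metabolite_id
    if pmf_id not in model.metabolites:
        raise PMFMisuseError("model has no PMF metabolite")

    produced = 0.0
    consumed = {"atp_synthesis": 0.0, "transport": 0.0, "sink": 0.0, "other": 0.0}
    for rxn in model.reactions.values():
        coef = rxn.stoichiometry.get(pmf_id)
        if not coef:
            continue
        flux = result.fluxes.get(rxn.id, 0.0)
        net = coef * flux
        if net > 0:
            produced += net
            continue
        if net == 0:
            continue
        amount = -net
        if rxn.annotations.get(ANN_SYNTHASE):
            consumed["atp_synthesis"] += amount
        elif rxn.annotations.get("pmf_sink") or rxn.id == PMF_SINK_ID:
            consumed["sink"] += amount
        elif rxn.is_transport:
            consumed["transport"] += amount
        else:
            consumed["other"] += amount
    total = sum(consumed.values())
    if total > 1e-12 and abs(total - produced) > 1e-6 * max(total, 1.0):
        raise PMFMisuseError(
            f"PMF not balanced: produced {produced:.6g}, consumed {total:.6g}"
        )
    rows = [
        {"category": cat, "pmf_flux": amt, "fraction": (amt / total if total else 0.0)}
        for cat, amt in consumed.items()
    ]
    return pd.DataFrame(rows)
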