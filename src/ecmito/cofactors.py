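"""Fe/S-cluster biosynthesis and cofactor incorporation bookkeeping.

Mitochondrial iron-sulfur cluster biogenesis is modeled in three stages:
(1) assembly of a [2Fe-2S] cluster on the Isu scaffold from ferrous iron and
cysteine-derived sulfur, with an NADPH-coupled two-electron reduction;
(2) transfer of the cluster to the Grx5 carrier (ATP-driven, mtHsp70 system);
(3) insertion into apo-targets, or condensation of two carrier-bound
[2Fe-2S] clusters into a [4Fe-4S] cluster.  Apo-proteins become catalytically
active holo-proteins only after incorporation, and cofactor demand of
proteins outside the model's scope is appended to the biomass reaction in
proportion to their measured abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .model_core import Metabolite, Model, ModelError, Reaction, ReferenceError_

logger = logging.getLogger(__name__)

COFACTORS = ("2Fe-2S", "4Fe-4S", "lipoate", "biotin", "heme_a", "ferroheme_b", "siroheme")

#: model species delivering each cofactor for incorporation
COFACTOR_SPECIES = {
    "2Fe-2S": "fes2_grx_mm",
    "4Fe-4S": "fes4_mm",
    "lipoate": "lipoate_mm",
    "biotin": "biotin_mm",
    "heme_a": "heme_a_mm",
    "ferroheme_b": "ferroheme_b_mm",
    "siroheme": "siroheme_mm",
}

#: iron atoms carried by each Fe-containing species (for conservation audits)
FE_CONTENT = {
    "fe2_mm": 1,
    "fes2_isu_mm": 2,
    "fes2_grx_mm": 2,
    "fes4_mm": 4,
}

S_CONTENT = {
    "cys_mm": 1,  # cysteine delivers the sulfur
    "s_nfs_mm": 1,
    "fes2_isu_mm": 2,
    "fes2_grx_mm": 2,
    "fes4_mm": 4,
}

#: Fe/S pathway species: (formula, charge, is_pseudo).  Clusters carry real
#: formulas so the stage reactions are elementally auditable.
_FES_SPECIES = {
    "s_nfs_mm": ("S", 0, False),
    "fes2_isu_mm": ("Fe2S2", 2, False),
    "fes2_grx_mm": ("Fe2S2", 2, False),
    "fes4_mm": ("Fe4S4", 2, False),
}


class CofactorConfigurationError(ModelError):
    """Required machinery missing from the Fe/S pathway tables."""


@dataclass
class CofactorSpec:
    cofactor: str
    stoichiometry: dict = field(default_factory=dict)  # protein_id -> count

    def __post_init__(self) -> None:
        if self.cofactor not in COFACTORS:
            raise ValueError(f"unknown cofactor {self.cofactor!r}")
        for pid, n in self.stoichiometry.items():
            if not (isinstance(n, int) and n > 0):
                raise ValueError(f"cofactor count for {pid} must be a positive integer")


@dataclass
class FeSPathwayStage:
    stage: str  # scaffold_synthesis | transfer_to_grx5 | target_insertion_or_4Fe4S
    reactions: list = field(default_factory=list)
    machinery: list = field(default_factory=list)  # (protein_id, kcat) pairs


STAGES = ("scaffold_synthesis", "transfer_to_grx5", "target_insertion_or_4Fe4S")
#: enzymes each stage needs, keyed by role name in the machinery table
STAGE_MACHINERY = {
    "scaffold_synthesis": ("NFS1", "ISU"),
    "transfer_to_grx5": ("FES_TRANSFER",),
    "target_insertion_or_4Fe4S": ("ISA",),
}


def build_fes_pathway(
    machinery_table: Mapping[str, str],
    kcat_table: Mapping[str, float],
) -> list:
    """Construct the three-stage Fe/S biosynthesis reactions.

    ``machinery_table`` maps the role names (NFS1 desulfurase, ISU scaffold,
    FES_TRANSFER chaperone system, ISA 4Fe-4S machinery) to protein ids;
    ``kcat_table`` gives their turnover numbers in 1/h.  Only kcat values
    measured under physiological electron donors belong here; in-vitro rates
    obtained with chemical reductants overestimate capacity.

    Iron and sulfur atoms are conserved across every stage (two carrier-bound
    [2Fe-2S] clusters condense into one [4Fe-4S]).
    """
    for stage, roles in STAGE_MACHINERY.items():
        for role in roles:
            if role not in machinery_table:
                raise CofactorConfigurationError(f"stage {stage}: missing machinery {role}")
            if machinery_table[role] not in kcat_table:
                raise CofactorConfigurationError(
                    f"no kcat for {machinery_table[role]} (role {role})"
                )

    def enz(role: str):
        pid = machinery_table[role]
        return (pid, kcat_table[pid])

    sulfur = Reaction(
        id="FES_SULFUR",
        name="cysteine desulfurase (persulfide sulfur mobilization)",
        stoichiometry={"cys_mm": -1, "ala_mm": 1, "s_nfs_mm": 1},
        enzymes=[enz("NFS1")],
        subsystem="fes_biosynthesis",
    )
    scaffold = Reaction(
        id="FES_SCAFFOLD",
        name="[2Fe-2S] assembly on the Isu scaffold (NADPH-coupled)",
        stoichiometry={
            "fe2_mm": -2,
            "s_nfs_mm": -2,
            "nadph_mm": -1,
            "nadp_mm": 1,
            "h_mm": 1,
            "fes2_isu_mm": 1,
        },
        enzymes=[enz("ISU")],
        subsystem="fes_biosynthesis",
    )
    transfer = Reaction(
        id="FES_TRANSFER",
        name="[2Fe-2S] transfer to glutaredoxin carrier (ATP-driven)",
        stoichiometry={
            "fes2_isu_mm": -1,
            "atp_mm": -1,
            "h2o_mm": -1,
            "fes2_grx_mm": 1,
            "adp_mm": 1,
            "h2po4_mm": 1,
        },
        enzymes=[enz("FES_TRANSFER")],
        subsystem="fes_biosynthesis",
    )
    fes4 = Reaction(
        id="FES_4FE4S",
        name="[4Fe-4S] synthesis from two carrier-bound [2Fe-2S] clusters",
        stoichiometry={
            "fes2_grx_mm": -2,
            "nadph_mm": -1,
            "nadp_mm": 1,
            "h_mm": 1,
            "fes4_mm": 1,
        },
        enzymes=[enz("ISA")],
        subsystem="fes_biosynthesis",
    )
    return [
        FeSPathwayStage("scaffold_synthesis", [sulfur, scaffold], [enz("NFS1"), enz("ISU")]),
        FeSPathwayStage("transfer_to_grx5", [transfer], [enz("FES_TRANSFER")]),
        FeSPathwayStage("target_insertion_or_4Fe4S", [fes4], [enz("ISA")]),
    ]


def audit_fe_conservation(stages: Iterable[FeSPathwayStage]) -> list:
    """Check Fe and S atom conservation of every pathway reaction."""
    violations = []
    for stage in stages:
        for rxn in stage.reactions:
            for label, content in (("Fe", FE_CONTENT), ("S", S_CONTENT)):
                net = sum(
                    coef * content.get(mid, 0) for mid, coef in rxn.stoichiometry.items()
                )
                if abs(net) > 1e-9:
                    violations.append(f"{rxn.id}: {label} imbalance {net:+g}")
    return violations


def add_fes_pathway(model: Model, stages: Iterable[FeSPathwayStage]) -> Model:
    """Insert the pathway reactions (and any new cluster species) into a model."""
    model = model.copy()
    for stage in stages:
        for rxn in stage.reactions:
            for mid in rxn.stoichiometry:
                if mid not in model.metabolites:
                    formula, charge, pseudo = _FES_SPECIES.get(mid, (None, 0, True))
                    model.add_metabolite(
                        Metabolite(mid, name=mid, compartment="mm", charge=charge,
                                   formula=formula, is_pseudo=pseudo)
                    )
            if rxn.id not in model.reactions:
                model.add_reaction(rxn.copy())
    return model


def add_cofactor_incorporation(model: Model, specs: Iterable[CofactorSpec]) -> Model:
    """Add apo + n cofactor -> holo reactions and rewire enzyme species.

    Each target protein must already exist as a located model species (the
    import layer creates it); catalysis is re-pointed at the holo form so
    flux through the enzyme's reactions forces cofactor synthesis.
    """
    model = model.copy()
    species_map = model.annotations.setdefault("enzyme_species", {})
    missing = []
    for spec in specs:
        for pid in spec.stoichiometry:
            if pid not in model.proteins:
                missing.append(pid)
    if missing:
        raise ReferenceError_(f"cofactor specs name absent proteins: {sorted(set(missing))}")

    for spec in specs:
        cof_species = COFACTOR_SPECIES[spec.cofactor]
        for pid, count in spec.stoichiometry.items():
            apo = species_map.get(pid)
            if apo is None or apo not in model.metabolites:
                raise ReferenceError_(
                    f"protein {pid} has no model species (run the import layer first)"
                )
            if cof_species not in model.metabolites:
                model.add_metabolite(
                    Metabolite(cof_species, name=cof_species, compartment="mm",
                               charge=0, is_pseudo=True)
                )
            holo = f"prot_{pid}_holo"
            if holo not in model.metabolites:
                model.add_metabolite(
                    Metabolite(
                        holo,
                        name=f"{pid} holo-form",
                        compartment=model.metabolites[apo].compartment,
                        charge=0,
                        is_pseudo=True,
                    )
                )
            rid = f"INCORP_{spec.cofactor.replace('-', '')}_{pid}"
            if rid not in model.reactions:
                model.add_reaction(
                    Reaction(
                        id=rid,
                        name=f"{spec.cofactor} incorporation into {pid}",
                        stoichiometry={apo: -1.0, cof_species: -float(count), holo: 1.0},
                        subsystem="cofactor_incorporation",
                        # the cofactor's atoms move into the (pseudo) holo-protein
                        annotations={"balance_exempt": True},
                    )
                )
            else:
                # protein with several cofactors: extend the existing reaction
                model.reactions[rid].stoichiometry[cof_species] = -float(count)
            species_map[pid] = holo
    return model


def compute_unmodeled_cofactor_demand(
    specs: Iterable[CofactorSpec],
    abundances: Mapping[str, float],
    modeled_ids: set,
    mu_independent: bool = True,
) -> dict:
    """Biomass coefficient additions for cofactors of unmodeled proteins.

    Per cofactor: sum of (abundance x count) over cofactor-bearing proteins
    outside ``modeled_ids``; mmol/gDW, appended to the biomass reaction so the
    demand scales with growth.
    """
    demand: dict = {}
    for spec in specs:
        total = 0.0
        for pid, count in spec.stoichiometry.items():
            if pid in modeled_ids:
                continue
            abundance = abundances.get(pid)
            if abundance is None:
                continue
            if abundance < 0:
                raise ValueError(f"negative abundance for {pid}")
            total += abundance * count
        if total:
            demand[spec.cofactor] = demand.get(spec.cofactor, 0.0) + total
    return demand


def append_demand_to_biomass(model: Model, demand: Mapping[str, float]) -> Model:
    """Subtract cofactor species from the biomass reaction per the demand map."""
    model = model.copy()
    biomass = model.biomass_reaction
    if biomass is None:
        raise ModelError("model has no biomass reaction")
    for cofactor, amount in demand.items():
        species = COFACTOR_SPECIES[cofactor]
        if species not in model.metabolites:
            model.add_metabolite(
                Metabolite(species, name=species, compartment="mm", charge=0, is_pseudo=True)
            )
        biomass.stoichiometry[species] = biomass.stoichiometry.get(species, 0.0) - amount
    return model
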