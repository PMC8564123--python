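"""Mitochondrial protein import: pathway assignment, energetics, reactions.

Nuclear-encoded mitochondrial proteins reach their compartment through one of
three machineries downstream of the TOM complex in the outer membrane: the
MIA disulfide relay (intermembrane-space proteins with twin cysteine motifs),
the TIM22 carrier translocase, and the TIM23 presequence pathway.  TIM23
substrates either stay in the inner membrane (stop transfer, or conservative
sorting via the matrix and the OXA insertase when their transmembrane
segments contain proline) or are pulled fully into the matrix by the PAM
motor at a cost of one ATP per 25 residues (the spacing of mtHsp70 binding
sites).  Crossing the inner membrane electrophoretically costs 0.9 PMF per
net positive charge of the translocated region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional

import pandas as pd

from .model_core import (
    Metabolite,
    Model,
    ModelError,
    ProteinRecord,
    Reaction,
)
from .pmf import PMFSpec, ensure_pmf_metabolite

__all__ = [
    "ProteinRecord",
    "ImportAssignment",
    "ImportMachineryComponent",
    "assign_import_pathway",
    "compute_matrix_import_atp_cost",
    "compute_import_pmf_cost",
    "build_import_reactions",
    "integrate_import",
    "estimate_import_kcat",
    "curated_kcat_table",
    "impute_protein_abundance",
    "PATHWAYS",
]

logger = logging.getLogger(__name__)

PATHWAYS = (
    "TOM_only",
    "TIM23_matrix",
    "TIM23_stop_transfer",
    "TIM23_conservative_sorting",
    "TIM22_carrier",
    "MIA",
)

MTHSP70_STEP = 25  # residues per ATP-consuming mtHsp70 binding cycle

#: machinery engaged by each pathway (TOM is the universal entry point)
PATHWAY_MACHINERY = {
    "TOM_only": ("TOM",),
    "TIM23_matrix": ("TOM", "TIM23", "PAM", "MPP"),
    "TIM23_stop_transfer": ("TOM", "TIM23", "MPP"),
    "TIM23_conservative_sorting": ("TOM", "TIM23", "PAM", "MPP", "OXA"),
    "TIM22_carrier": ("TOM", "SMALL_TIM", "TIM22"),
    "MIA": ("TOM", "MIA"),
}

PRESEQUENCE_PEPTIDE_ID = "preseq_peptide_mm"
PEPTIDE_DEGRADATION_ID = "PRESEQ_DEGRADATION"


class UnassignableProteinError(ModelError):
    """No import pathway rule covers this protein."""


class ImportConfigurationError(ModelError):
    """Required machinery component missing."""


@dataclass
class ImportAssignment:
    protein_id: str
    pathway: str
    atp_cost: int = 0
    pmf_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if self.atp_cost < 0 or self.pmf_cost < 0:
            raise ValueError("import costs must be non-negative")
        if self.pathway in ("TOM_only", "MIA") and self.atp_cost != 0:
            raise ValueError(f"{self.pathway} import is ATP-free")


@dataclass
class ImportMachineryComponent:
    """One translocation machine (complexes lumped into a single entity)."""

    id: str
    subunits: list = field(default_factory=list)
    kcat: float = 0.0  # 1/h, per import event
    substrates: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# pathway assignment
# ---------------------------------------------------------------------------

def assign_import_pathway(protein: ProteinRecord) -> str:
    """Decide the import pathway from compartment, motifs and TM segments.

    Inner-membrane presequence proteins go to conservative sorting when any
    transmembrane segment contains a proline, else to stop transfer.
    """
    comp = protein.compartment
    if comp not in {
        "mito_outer_membrane",
        "mito_intermembrane_space",
        "mito_inner_membrane",
        "mito_matrix",
    }:
        raise UnassignableProteinError(
            f"{protein.id}: compartment {comp!r} is not mitochondrial"
        )
    if comp == "mito_outer_membrane":
        return "TOM_only"
    if comp == "mito_intermembrane_space":
        if protein.cysteine_motif in ("twin-CX9C", "twin-CX3C"):
            return "MIA"
        if protein.presequence_length > 0:
            return "TIM23_stop_transfer"
        raise UnassignableProteinError(
            f"{protein.id}: IMS protein without cysteine motif or presequence"
        )
    if comp == "mito_inner_membrane":
        if protein.is_carrier:
            return "TIM22_carrier"
        if any(
            "P" in protein.sequence[start - 1 : end]
            for start, end in protein.tm_segments
        ):
            return "TIM23_conservative_sorting"
        return "TIM23_stop_transfer"
    # matrix
    return "TIM23_matrix"


# ---------------------------------------------------------------------------
# energetics
# ---------------------------------------------------------------------------

def compute_matrix_import_atp_cost(length: int, rounding: str = "ceil") -> float:
    """ATP hydrolyzed by the PAM motor for ``length`` imported residues.

    One ATP per 25-residue mtHsp70 binding interval; discrete cycles, hence
    the ceiling (``rounding="linear"`` gives the un-rounded length/25).
    """
    if length < 0:
        raise ValueError(f"imported length must be >= 0, got {length}")
    if rounding == "ceil":
        return float(math.ceil(length / MTHSP70_STEP))
    if rounding == "linear":
        return length / MTHSP70_STEP
    raise ValueError(f"unknown rounding mode {rounding!r}")


def imported_region(protein: ProteinRecord, pathway: str) -> str:
    """Sequence region crossing the inner membrane electrophoretically."""
    if pathway == "TIM23_matrix":
        return protein.sequence  # presequence first, mature part follows
    if pathway == "TIM23_stop_transfer":
        return protein.presequence
    if pathway == "TIM23_conservative_sorting":
        tm = "".join(
            protein.sequence[start - 1 : end] for start, end in protein.tm_segments
        )
        return protein.presequence + tm
    return ""  # TOM_only, MIA, TIM22 carriers: no Delta-psi charge cost applied


def net_positive_charge(region: str) -> int:
    """K+R minus D+E, floored at zero (His and termini excluded)."""
    unknown = set(region) - set("ACDEFGHIKLMNPQRSTVWY")
    if unknown:
        logger.warning("ignoring non-standard residues %s", sorted(unknown))
    positive = sum(region.count(a) for a in "KR")
    negative = sum(region.count(a) for a in "DE")
    net = positive - negative
    if net < 0:
        logger.warning("net negative imported region (%d); PMF cost floored at 0", net)
    return max(0, net)


def compute_import_pmf_cost(
    protein: ProteinRecord,
    spec: PMFSpec = None,
    pathway: Optional[str] = None,
) -> float:
    """PMF pseudo-metabolites dissipated importing one protein molecule.

    0.9 (``delta_psi_fraction``) per net positive charge of the region that
    crosses the inner membrane.
    """
    spec = spec or PMFSpec()
    if not protein.sequence:
        raise ValueError(f"{protein.id}: empty sequence")
    pathway = pathway or assign_import_pathway(protein)
    region = imported_region(protein, pathway)
    return net_positive_charge(region) * spec.delta_psi_fraction


def atp_cost_for(protein: ProteinRecord, pathway: str, rounding: str = "ceil") -> int:
    """Pathway-dependent PAM ATP cost for one import event."""
    if pathway == "TIM23_matrix":
        return int(compute_matrix_import_atp_cost(len(protein.sequence), rounding))
    if pathway == "TIM23_conservative_sorting":
        tm_len = sum(end - start + 1 for start, end in protein.tm_segments)
        return int(compute_matrix_import_atp_cost(tm_len, rounding))
    return 0


def make_assignment(protein: ProteinRecord, spec: PMFSpec = None) -> ImportAssignment:
    pathway = assign_import_pathway(protein)
    return ImportAssignment(
        protein_id=protein.id,
        pathway=pathway,
        atp_cost=atp_cost_for(protein, pathway),
        pmf_cost=compute_import_pmf_cost(protein, spec, pathway),
    )


# ---------------------------------------------------------------------------
# reaction construction
# ---------------------------------------------------------------------------

def protein_species_id(protein_id: str, where: str) -> str:
    return f"prot_{protein_id}_{where}"


def build_import_reactions(
    protein: ProteinRecord,
    assignment: ImportAssignment,
    machinery: Mapping[str, ImportMachineryComponent],
    spec: PMFSpec = None,
) -> list:
    """Template reaction(s) translocating one protein to its compartment.

    The reaction consumes the cytosolic protein species and the import
    energetics (matrix ATP hydrolysis by the PAM motor, PMF for the charged
    region), produces the located species, engages the pathway machinery as
    kcat-coupled enzymes, and (for presequence substrates) releases the
    cleaved presequence peptide for degradation.
    """
    spec = spec or PMFSpec()
    needed = PATHWAY_MACHINERY[assignment.pathway]
    missing = [m for m in needed if m not in machinery]
    if missing:
        raise ImportConfigurationError(
            f"{protein.id}: missing machinery component(s) {missing}"
        )
    stoich: Dict[str, float] = {
        protein_species_id(protein.id, "c"): -1.0,
        protein_species_id(protein.id, "loc"): 1.0,
    }
    n_atp = assignment.atp_cost
    if n_atp:
        stoich.update(
            {
                "atp_mm": -float(n_atp),
                "h2o_mm": -float(n_atp),
                "adp_mm": float(n_atp),
                "h2po4_mm": float(n_atp),
            }
        )
    if assignment.pmf_cost:
        stoich[spec.pmf_metabolite_id] = -assignment.pmf_cost
    if assignment.pathway.startswith("TIM23") and protein.presequence_length > 0:
        stoich[PRESEQUENCE_PEPTIDE_ID] = 1.0
    rxn = Reaction(
        id=f"IMPORT_{protein.id}",
        name=f"import of {protein.id} ({assignment.pathway})",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        enzymes=[(machinery[m].id, machinery[m].kcat) for m in needed],
        subsystem="protein_import",
        annotations={"import_pathway": assignment.pathway},
    )
    return [rxn]


def integrate_import(
    model: Model,
    machinery: Mapping[str, ImportMachineryComponent],
    spec: PMFSpec = None,
    proteins: Optional[Iterable[str]] = None,
) -> Model:
    """Add protein species and import reactions for mitochondrial proteins.

    Creates the cytosolic and located pseudo-species for every mitochondrial
    protein in ``model.proteins`` (or the subset ``proteins``), the import
    reactions, and a lumped zero-cost presequence-peptide degradation
    reaction.  Records the active enzyme species per protein in the model
    annotations for the enzyme-constraint layer.
    """
    spec = spec or PMFSpec()
    model = model.copy()
    ensure_pmf_metabolite(model, spec)
    species_map = model.annotations.setdefault("enzyme_species", {})
    ids = list(proteins) if proteins is not None else list(model.proteins)

    def _add_species(sid: str, compartment: str) -> None:
        if sid not in model.metabolites:
            model.add_metabolite(
                Metabolite(sid, name=sid, compartment=compartment, charge=0, is_pseudo=True)
            )

    imported_any = False
    for pid in ids:
        protein = model.proteins[pid]
        if protein.annotations.get("machinery_component"):
            # lumped translocation machines are not themselves run through the
            # import templates; they draw from the pool as cytosol-made entities
            _add_species(protein_species_id(pid, "c"), "c")
            species_map[pid] = protein_species_id(pid, "c")
            continue
        if protein.compartment not in {
            "mito_outer_membrane",
            "mito_intermembrane_space",
            "mito_inner_membrane",
            "mito_matrix",
        }:
            _add_species(protein_species_id(pid, "c"), "c")
            species_map[pid] = protein_species_id(pid, "c")
            continue
        assignment = make_assignment(protein, spec)
        _add_species(protein_species_id(pid, "c"), "c")
        loc_comp = {
            "mito_outer_membrane": "mom",
            "mito_intermembrane_space": "ims",
            "mito_inner_membrane": "mim",
            "mito_matrix": "mm",
        }[protein.compartment]
        _add_species(protein_species_id(pid, "loc"), loc_comp)
        if assignment.pathway.startswith("TIM23") and protein.presequence_length > 0:
            _add_species(PRESEQUENCE_PEPTIDE_ID, "mm")
            imported_any = True
        for rxn in build_import_reactions(protein, assignment, machinery, spec):
            if rxn.id not in model.reactions:
                model.add_reaction(rxn)
        species_map[pid] = protein_species_id(pid, "loc")
        model.proteins[pid].annotations["import_pathway"] = assignment.pathway
        model.proteins[pid].annotations["import_atp_cost"] = assignment.atp_cost
        model.proteins[pid].annotations["import_pmf_cost"] = assignment.pmf_cost

    if imported_any and PEPTIDE_DEGRADATION_ID not in model.reactions:
        model.add_reaction(
            Reaction(
                id=PEPTIDE_DEGRADATION_ID,
                name="presequence peptide degradation (lumped, ATP-free)",
                stoichiometry={PRESEQUENCE_PEPTIDE_ID: -1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                subsystem="protein_import",
            )
        )
    return model


# ---------------------------------------------------------------------------
# turnover estimation and curated rates
# ---------------------------------------------------------------------------

def estimate_import_kcat(
    component: ImportMachineryComponent,
    substrate_abundances: Mapping[str, float],
    mu: float,
) -> float:
    """Estimate a translocase turnover from absolute abundances.

    kcat = mu * sum(substrate abundances) / mean(subunit abundances): at
    steady state the machine must import the whole standing pool of its
    substrates once per doubling (degradation neglected).  Units 1/h.
    """
    substrates = [s for s in component.substrates if s in substrate_abundances]
    total = sum(substrate_abundances[s] for s in substrates)
    if not component.substrates or total == 0.0:
        logger.warning("component %s has no measured substrates; kcat set to 0", component.id)
        return 0.0
    subunit_levels = [
        substrate_abundances[s] for s in component.subunits if s in substrate_abundances
    ]
    mean_e = sum(subunit_levels) / len(subunit_levels) if subunit_levels else 0.0
    if mean_e <= 0:
        raise ZeroDivisionError(
            f"component {component.id}: mean subunit abundance is zero"
        )
    return mu * total / mean_e


TRANSLATION_RATE_PER_S = 10.0   # TOM/OXA assumed co-translational rate
TIM23_RATE_AA_PER_S = 9.0       # measured translocation speed, aa/s
CARRIER_METABOLIC_KCAT_PER_S = 70.9  # average metabolic enzyme turnover


def curated_kcat_table(
    median_protein_length: float,
    overrides: Optional[Mapping[str, float]] = None,
) -> dict:
    """Curated translocation rates per machinery component, in 1/h.

    TOM and OXA run at the translation rate (10/s); TIM23+PAM translocate at
    9 aa/s, i.e. 9/median_length proteins per second; components without a
    literature rate default to the translation rate.  User overrides win.
    """
    if median_protein_length <= 0:
        raise ValueError("median protein length must be positive")
    tim23 = TIM23_RATE_AA_PER_S / median_protein_length
    table = {
        "TOM": TRANSLATION_RATE_PER_S * 3600.0,
        "OXA": TRANSLATION_RATE_PER_S * 3600.0,
        "TIM23": tim23 * 3600.0,
        "PAM": tim23 * 3600.0,
        "MPP": TRANSLATION_RATE_PER_S * 3600.0,
        "TIM22": TRANSLATION_RATE_PER_S * 3600.0,
        "SMALL_TIM": TRANSLATION_RATE_PER_S * 3600.0,
        "MIA": TRANSLATION_RATE_PER_S * 3600.0,
    }
    for key, value in (overrides or {}).items():
        table[key] = value
    return table


# ---------------------------------------------------------------------------
# abundance imputation
# ---------------------------------------------------------------------------

def impute_protein_abundance(
    proteomics: pd.DataFrame,
    transcriptomics: pd.DataFrame,
    complex_membership: Mapping[str, str],
) -> pd.DataFrame:
    """Fill missing protein abundances from mRNA via complex-mate ratios.

    For a protein missing in ``proteomics`` but present in
    ``transcriptomics``, its abundance is the mRNA level times the mean
    protein/mRNA ratio over the measured subunits of the same complex.  Input
    frames need columns ``protein_id`` and ``abundance``; the result adds an
    ``imputed`` flag, and fully unmeasured complexes stay missing (flagged
    NaN).
    """
    prot = proteomics.set_index("protein_id")["abundance"]
    mrna = transcriptomics.set_index("protein_id")["abundance"]

    ratios: Dict[str, list] = {}
    for pid, cplx in complex_membership.items():
        if pid in prot.index and pid in mrna.index and mrna[pid] > 0:
            ratios.setdefault(cplx, []).append(prot[pid] / mrna[pid])

    rows = []
    for pid, cplx in complex_membership.items():
        if pid in prot.index:
            rows.append({"protein_id": pid, "abundance": prot[pid], "imputed": False})
        elif pid in mrna.index and cplx in ratios:
            mean_ratio = sum(ratios[cplx]) / len(ratios[cplx])
            rows.append(
                {"protein_id": pid, "abundance": mrna[pid] * mean_ratio, "imputed": True}
            )
        else:
            logger.warning("no measured subunit for complex %s; %s left missing", cplx, pid)
            rows.append({"protein_id": pid, "abundance": float("nan"), "imputed": True})
    return pd.DataFrame(rows)
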