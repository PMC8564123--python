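"""Core data model for compartmentalized stoichiometric networks with enzymes.

The in-memory containers here are deliberately richer than a plain SBML model:
reactions carry ``(protein, kcat)`` pairs, metabolites carry a pseudo flag
(PMF, enzyme pool, presequence peptides), and compartments carry a mitochondrial
*kind* so that membrane-crossing logic (PMF coupling, import pathway
assignment) can reason about topology.  The canonical serialization is a
versioned JSON dialect; SBML Level 3 + fbc is supported for interchange
(:mod:`ecmito.io`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import cobra

logger = logging.getLogger(__name__)

COMPARTMENT_KINDS = frozenset(
    {
        "cytosol",
        "mito_outer_membrane",
        "mito_intermembrane_space",
        "mito_inner_membrane",
        "mito_matrix",
        "extracellular",
        "pseudo",
    }
)

MITO_KINDS = frozenset(
    {
        "mito_outer_membrane",
        "mito_intermembrane_space",
        "mito_inner_membrane",
        "mito_matrix",
    }
)

MEMBRANE_KINDS = frozenset({"mito_outer_membrane", "mito_inner_membrane"})


class ModelError(Exception):
    """Base class for model construction/validation problems."""


class ReferenceError_(ModelError):
    """A reaction or spec refers to an entity that is not in the model."""


class FormatError(ModelError):
    """A file could not be parsed as the requested format."""


class ValidationError(ModelError):
    """A model failed structural validation."""


class AmbiguityError(ModelError):
    """A rule cannot decide between conflicting inputs."""


class InfeasibleCompositionError(ModelError):
    """A biomass composition cannot be realized (mass budget exceeded)."""


@dataclass
class Compartment:
    id: str
    name: str = ""
    kind: str = "cytosol"

    def __post_init__(self) -> None:
        if self.kind not in COMPARTMENT_KINDS:
            raise ModelError(f"unknown compartment kind {self.kind!r} for {self.id!r}")


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    charge: Optional[int] = None
    formula: Optional[str] = None
    is_pseudo: bool = False

    @property
    def elements(self) -> Optional[dict]:
        if not self.formula:
            return None
        return cobra.Metabolite(self.id, formula=self.formula).elements


@dataclass
class Reaction:
    """A (possibly enzyme-coupled) reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  ``enzymes`` lists ``(protein_id, kcat)`` pairs with kcat in
    1/h; a multi-entry list means a complex whose subunits are all engaged
    stoichiometrically.
    """

    id: str
    stoichiometry: dict = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    enzymes: list = field(default_factory=list)
    subsystem: str = ""
    name: str = ""
    is_exchange: bool = False
    is_transport: bool = False
    is_biomass: bool = False
    annotations: dict = field(default_factory=dict)

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            enzymes=[tuple(e) for e in self.enzymes],
            subsystem=self.subsystem,
            name=self.name,
            is_exchange=self.is_exchange,
            is_transport=self.is_transport,
            is_biomass=self.is_biomass,
            annotations=dict(self.annotations),
        )


@dataclass
class ProteinRecord:
    """One protein: sequence-derived properties plus model wiring.

    ``mw`` is in g/mmol (i.e. kDa); ``tm_segments`` are 1-based inclusive
    residue intervals; ``presequence_length`` is 0 for proteins without a
    cleavable targeting signal.
    """

    id: str
    sequence: str = ""
    mw: float = 0.0
    compartment: str = "cytosol"
    presequence_length: int = 0
    tm_segments: list = field(default_factory=list)
    cysteine_motif: Optional[str] = None  # twin-CX9C, twin-CX3C or None
    is_carrier: bool = False
    abundance: Optional[float] = None  # mmol/gDW
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for start, end in self.tm_segments:
            if not (1 <= start <= end <= max(len(self.sequence), 1)):
                raise ModelError(
                    f"TM segment ({start},{end}) outside sequence bounds for {self.id!r}"
                )

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.presequence_length:]

    @property
    def presequence(self) -> str:
        return self.sequence[: self.presequence_length]


@dataclass
class Model:
    """A compartmentalized stoichiometric model with protein records."""

    id: str = "model"
    compartments: dict = field(default_factory=dict)
    metabolites: dict = field(default_factory=dict)
    reactions: dict = field(default_factory=dict)
    proteins: dict = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------
    def add_compartment(self, comp: Compartment) -> None:
        if comp.id in self.compartments:
            raise ModelError(f"duplicate compartment id {comp.id!r}")
        self.compartments[comp.id] = comp

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            raise ReferenceError_(
                f"metabolite {met.id!r} references unknown compartment {met.compartment!r}"
            )
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise ReferenceError_(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                )
        self.reactions[rxn.id] = rxn

    def add_protein(self, prot: ProteinRecord) -> None:
        if prot.id in self.proteins:
            raise ModelError(f"duplicate protein id {prot.id!r}")
        self.proteins[prot.id] = prot

    # -- queries --------------------------------------------------------------
    @property
    def biomass_reaction(self) -> Optional[Reaction]:
        hits = [r for r in self.reactions.values() if r.is_biomass]
        if len(hits) > 1:
            raise ValidationError("multiple biomass reactions present")
        return hits[0] if hits else None

    def compartment_kind(self, metabolite_id: str) -> str:
        met = self.metabolites[metabolite_id]
        return self.compartments[met.compartment].kind

    def copy(self) -> "Model":
        import copy as _copy

        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(model: Model) -> list:
    """Structural validation; returns a list of human-readable violations.

    Checks dangling references, bound sanity, biomass uniqueness and, for
    reactions whose (non-pseudo) metabolites all carry formulas, elemental
    balance.  Charge balance is checked only for reactions confined to a
    single compartment: transport legitimately separates charge, and the PMF
    pseudo-metabolite carries the energetics of that separation.
    """
    violations: list = []
    for met in model.metabolites.values():
        if met.compartment not in model.compartments:
            violations.append(f"metabolite {met.id}: unknown compartment {met.compartment}")
    n_biomass = sum(1 for r in model.reactions.values() if r.is_biomass)
    if n_biomass > 1:
        violations.append(f"{n_biomass} biomass reactions present (expected at most 1)")

    for rxn in model.reactions.values():
        if not any(c != 0 for c in rxn.stoichiometry.values()):
            violations.append(f"reaction {rxn.id}: no nonzero coefficient")
        if rxn.lower_bound > rxn.upper_bound:
            violations.append(
                f"reaction {rxn.id}: lower_bound {rxn.lower_bound} > upper_bound {rxn.upper_bound}"
            )
        for mid in rxn.stoichiometry:
            if mid not in model.metabolites:
                violations.append(f"reaction {rxn.id}: unknown metabolite {mid}")
        for pid, kcat in rxn.enzymes:
            if pid not in model.proteins:
                violations.append(f"reaction {rxn.id}: unknown enzyme {pid}")
            if kcat <= 0:
                violations.append(f"reaction {rxn.id}: non-positive kcat for {pid}")
        if rxn.is_exchange:
            continue
        violations.extend(_balance_violations(model, rxn))
    return violations


def _balance_violations(model: Model, rxn: Reaction) -> list:
    out: list = []
    if rxn.annotations.get("balance_exempt"):
        return out
    real = [
        (mid, coef)
        for mid, coef in rxn.stoichiometry.items()
        if mid in model.metabolites and not model.metabolites[mid].is_pseudo
    ]
    if not real:
        return out
    mets = [model.metabolites[mid] for mid, _ in real]
    if any(m.formula is None for m in mets):
        return out
    totals: dict = {}
    for (mid, coef), met in zip(real, mets):
        for el, n in met.elements.items():
            totals[el] = totals.get(el, 0.0) + coef * n
    bad = {el: v for el, v in totals.items() if abs(v) > 1e-6}
    if bad:
        out.append(f"reaction {rxn.id}: elemental imbalance {bad}")
    comps = {met.compartment for met in mets}
    if len(comps) == 1 and all(m.charge is not None for m in mets):
        qtot = sum(coef * model.metabolites[mid].charge for mid, coef in real)
        if abs(qtot) > 1e-6:
            out.append(f"reaction {rxn.id}: charge imbalance {qtot:+g}")
    return out


# ---------------------------------------------------------------------------
# complex compartment assignment
# ---------------------------------------------------------------------------

def assign_complex_compartment(subunit_compartments: Sequence[str]) -> str:
    """Assign a multi-subunit complex to a single mitochondrial compartment.

    If any subunit sits in a membrane the whole complex is assigned to that
    membrane (so it can touch metabolites on both sides).  Subunits spanning
    both membranes, or disagreeing soluble compartments, are an error: the
    assignment rule does not cover them.
    """
    kinds = list(subunit_compartments)
    if not kinds:
        raise AmbiguityError("empty subunit compartment list")
    unknown = [k for k in kinds if k not in MITO_KINDS]
    if unknown:
        raise AmbiguityError(f"non-mitochondrial compartment kinds: {unknown}")
    membranes = sorted({k for k in kinds if k in MEMBRANE_KINDS})
    if len(membranes) > 1:
        raise AmbiguityError(f"complex spans both membranes: {membranes}")
    if membranes:
        return membranes[0]
    soluble = sorted(set(kinds))
    if len(soluble) > 1:
        raise AmbiguityError(f"irreconcilable soluble compartments: {soluble}")
    return soluble[0]


# ---------------------------------------------------------------------------
# biomass lipid composition
# ---------------------------------------------------------------------------

def update_biomass_lipids(
    primary_lipids: Mapping[str, float],
    secondary_lipids: Mapping[str, float],
    molecular_weights: Mapping[str, float],
    total_lipid_fraction: float,
) -> dict:
    """Merge two lipid composition datasets into biomass coefficients.

    ``primary_lipids`` are measured masses (mg/gDW) and are kept as-is.
    ``secondary_lipids`` are mol fractions (mol/mol); species present only in
    the secondary table share the residual lipid mass (``total_lipid_fraction``
    * 1000 mg/gDW minus the primary mass) proportionally to their mass-weighted
    mol fractions.  Returns ``{species: coefficient}`` in mmol/gDW; the
    returned masses sum exactly to the total lipid mass.
    """
    if not (0 < total_lipid_fraction <= 1):
        raise ValueError(f"total_lipid_fraction must be in (0, 1], got {total_lipid_fraction}")
    total_mass = total_lipid_fraction * 1000.0  # mg/gDW
    primary_mass = float(sum(primary_lipids.values()))
    if primary_mass > total_mass + 1e-9:
        raise InfeasibleCompositionError(
            f"primary lipid mass {primary_mass} mg/gDW exceeds total lipid mass {total_mass} mg/gDW"
        )
    residual = total_mass - primary_mass

    secondary_only = {}
    for sp, molfrac in secondary_lipids.items():
        if sp in primary_lipids:
            logger.info(
                "lipid species %s present in both datasets; keeping primary mass", sp
            )
            continue
        if sp not in molecular_weights:
            raise ValueError(f"no molecular weight for secondary lipid species {sp!r}")
        secondary_only[sp] = molfrac

    masses = {sp: m for sp, m in primary_lipids.items()}
    weight_sum = sum(f * molecular_weights[sp] for sp, f in secondary_only.items())
    for sp, f in secondary_only.items():
        share = (f * molecular_weights[sp]) / weight_sum if weight_sum > 0 else 0.0
        masses[sp] = residual * share

    coefficients = {}
    for sp, mass in masses.items():
        mw = molecular_weights.get(sp)
        if mw is None:
            raise ValueError(f"no molecular weight for lipid species {sp!r}")
        coefficients[sp] = mass / mw  # mg/gDW / (g/mol) == mmol/gDW
    if secondary_only:
        assert math.isclose(sum(masses.values()), total_mass, rel_tol=0, abs_tol=1e-9)
    return coefficients
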