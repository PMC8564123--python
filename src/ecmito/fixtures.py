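"""Self-contained toy yeast core network and synthetic data generators.

The toy model is a desk-scale, mass/charge-balanced stand-in for a
genome-scale yeast network: lumped glycolysis, fermentation branches
(ethanol, acetate, glycerol, pyruvate), pyruvate transport, a lumped TCA
cycle, internal/external NADH dehydrogenases (no proton pumping), succinate
dehydrogenase, complex III (+4 PMF per electron pair), complex IV (+2), ATP
synthase (-3 PMF per ATP), the ADP/ATP translocase (-0.9) and phosphate
carrier (-0.1), a three-pool biomass reaction with polymerization costs, a
maintenance reaction, and a curated set of mitochondrial proteins spanning
all import pathways plus Fe/S, lipoate, biotin and heme-a requiring enzymes.

The electron-transport stoichiometry (6 PMF per NADH electron pair) makes
the theoretical maximum P/O an analytic property of the fixture:
6 / (3 + 0.9 + 0.1) = 1.5.

Everything is deterministic under the seed; the same seed produces
byte-identical serialized fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cofactors import CofactorSpec, add_fes_pathway, add_cofactor_incorporation, build_fes_pathway
from .ec_constraints import EnzymePool, apply_enzyme_constraints, apply_pool_constraint
from .io import model_to_dict
from .model_core import Compartment, Metabolite, Model, ProteinRecord, Reaction
from .pmf import PMFSpec, add_pmf_sink, apply_pmf_coupling
from .protein_import import (
    ImportMachineryComponent,
    assign_import_pathway,
    curated_kcat_table,
    integrate_import,
)

H = 3600.0  # 1/s -> 1/h

ETC_PMF_PER_NADH_PAIR = 6  # complex III (4) + complex IV (2)
DEFAULT_GAEC = 18.0        # fitted (non-polymerization) ATP cost, mmol/gDW
DEFAULT_NGAM = 0.7         # non-growth maintenance, mmol ATP/gDW/h
BIOMASS_COMPOSITION = {"protein_pool_c": 0.46, "carb_pool_c": 0.40, "lipid_pool_c": 0.08}
POLYMERIZATION_ATP = {"protein_pool_c": 4.0, "carb_pool_c": 1.0, "lipid_pool_c": 1.0}

_RESIDUE_MASS = {  # average residue masses, Da
    "A": 71.08, "C": 103.14, "D": 115.09, "E": 129.12, "F": 147.18,
    "G": 57.05, "H": 137.14, "I": 113.16, "K": 128.17, "L": 113.16,
    "M": 131.19, "N": 114.10, "P": 97.12, "Q": 128.13, "R": 156.19,
    "S": 87.08, "T": 101.10, "V": 99.13, "W": 186.21, "Y": 163.18,
}


def sequence_mw(sequence: str) -> float:
    """Molecular weight in g/mmol (kDa) from an amino-acid sequence."""
    return (sum(_RESIDUE_MASS[a] for a in sequence) + 18.02) / 1000.0


@dataclass
class FixtureManifest:
    seed: int
    reaction_count: int = 0
    metabolite_count: int = 0
    protein_count: int = 0
    etc_pmf_per_nadh_pair: int = ETC_PMF_PER_NADH_PAIR
    polymerization_atp: float = 0.0
    gaec: float = DEFAULT_GAEC
    ngam: float = DEFAULT_NGAM
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

_HYDROPHOBIC = "LAVIF"
_NEUTRAL = "ASTGNQLVIMFYW"


def _draw(rng, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _presequence(rng, length: int) -> str:
    # cleavable targeting signals are positively charged and D/E-poor
    out = []
    for _ in range(length):
        out.append("KR"[rng.integers(0, 2)] if rng.random() < 0.35 else _draw(rng, "ASLQT", 1))
    return "".join(out)


def _body(rng, length: int, extra_kr: int = 0, extra_de: int = 0) -> str:
    seq = list(_draw(rng, _NEUTRAL, length))
    pos = rng.permutation(length)
    k = 0
    for _ in range(extra_kr):
        seq[pos[k]] = "KR"[rng.integers(0, 2)]; k += 1
    for _ in range(extra_de):
        seq[pos[k]] = "DE"[rng.integers(0, 2)]; k += 1
    return "".join(seq)


def _with_tm(rng, seq: str, n_tm: int, tm_len: int = 19, proline: bool = False):
    """Overwrite evenly spaced windows with hydrophobic TM runs."""
    seq = list(seq)
    segments = []
    gap = max(1, (len(seq) - n_tm * tm_len) // (n_tm + 1))
    pos = gap
    for _ in range(n_tm):
        run = list(_draw(rng, _HYDROPHOBIC, tm_len))
        if proline:
            run[tm_len // 2] = "P"
        seq[pos : pos + tm_len] = run
        segments.append((pos + 1, pos + tm_len))
        pos += tm_len + gap
    return "".join(seq), segments


def _twin_cx9c(rng, length: int) -> str:
    body = list(_draw(rng, "ASTGNQ", length))
    for start in (5, 25):
        body[start] = "C"
        body[start + 10] = "C"
    return "".join(body)


# ---------------------------------------------------------------------------
# curated toy proteome
# ---------------------------------------------------------------------------

def _toy_proteins(rng) -> dict:
    """Curated protein set of the toy network (deterministic given rng)."""
    out: dict = {}

    def add(pid, compartment, sequence, preseq=0, tm=None, motif=None,
            carrier=False, ann=None):
        out[pid] = ProteinRecord(
            id=pid, sequence=sequence, mw=sequence_mw(sequence),
            compartment=compartment, presequence_length=preseq,
            tm_segments=tm or [], cysteine_motif=motif, is_carrier=carrier,
            annotations=ann or {},
        )

    # cytosolic enzymes
    for pid, n in [("GLY1", 420), ("PDC1", 250), ("ADH1", 180), ("ALD1", 240),
                   ("GPD1", 200), ("ACS1", 300), ("FBP1", 330), ("RIB1", 500),
                   ("JEN1", 410)]:
        add(pid, "cytosol", _body(rng, n, extra_kr=8, extra_de=8))

    # outer membrane / IMS
    add("TOM40", "mito_outer_membrane", _body(rng, 120, extra_kr=3, extra_de=3))
    add("MIA40", "mito_intermembrane_space", _twin_cx9c(rng, 90), motif="twin-CX9C")
    add("TIM10", "mito_intermembrane_space", _twin_cx9c(rng, 80), motif="twin-CX9C")

    # inner-membrane presequence proteins (stop transfer: proline-free TMs)
    for pid, n, n_tm in [("TIM23_1", 200, 2), ("TIM50", 240, 1),
                         ("SDH1", 260, 1), ("QCR2", 220, 1), ("NDE1", 280, 1)]:
        pre = _presequence(rng, 18)
        body, segs = _with_tm(rng, _body(rng, n, extra_kr=4, extra_de=4), n_tm)
        segs = [(s + len(pre), e + len(pre)) for s, e in segs]
        add(pid, "mito_inner_membrane", pre + body, preseq=len(pre), tm=segs)

    # conservative sorting: proline-containing TMs, re-inserted by OXA
    for pid, n in [("OXA1", 300), ("COX1", 320), ("NDI1", 290)]:
        pre = _presequence(rng, 22)
        body, segs = _with_tm(rng, _body(rng, n, extra_kr=5, extra_de=3), 1, proline=True)
        segs = [(s + len(pre), e + len(pre)) for s, e in segs]
        add(pid, "mito_inner_membrane", pre + body, preseq=len(pre), tm=segs)

    # carriers (TIM22 pathway, no presequence)
    for pid in ["AAC1", "PIC1", "PYRC", "TIM22_1"]:
        body, segs = _with_tm(rng, _body(rng, 300, extra_kr=6, extra_de=4), 3)
        add(pid, "mito_inner_membrane", body, tm=segs, carrier=True)

    # matrix proteins (TIM23 presequence pathway, PAM-driven)
    for pid, n, kr, de in [("PDA1", 380, 12, 6), ("FUM1", 330, 10, 6),
                           ("ATP1", 350, 10, 8), ("PYC1", 400, 10, 8),
                           ("MPP1", 310, 8, 6), ("PAM18", 160, 6, 4),
                           ("ISU1", 140, 6, 4), ("GRX5", 130, 5, 4),
                           ("ISA1", 150, 5, 4), ("NFS1", 330, 8, 6),
                           ("SSQ1", 300, 8, 6)]:
        pre = _presequence(rng, 20)
        add(pid, "mito_matrix", pre + _body(rng, n, extra_kr=kr, extra_de=de),
            preseq=len(pre))

    # lumped translocation machines (complex MW = sum of subunits)
    machines = {
        "TOM": ["TOM40"], "TIM23": ["TIM23_1", "TIM50"], "PAM": ["PAM18", "SSQ1"],
        "MPP": ["MPP1"], "TIM22": ["TIM22_1"], "MIA": ["MIA40"],
        "OXA": ["OXA1"], "SMALL_TIM": ["TIM10"],
    }
    for cid, subunits in machines.items():
        mw = sum(out[s].mw for s in subunits)
        comp = out[subunits[0]].compartment
        out[cid] = ProteinRecord(
            id=cid, sequence="", mw=mw, compartment=comp,
            annotations={"machinery_component": True, "subunits": subunits},
        )
    return out


#: cofactor requirements of the modeled toy enzymes
TOY_COFACTOR_SPECS = [
    CofactorSpec("2Fe-2S", {"SDH1": 1}),
    CofactorSpec("4Fe-4S", {"FUM1": 1}),
    CofactorSpec("lipoate", {"PDA1": 1}),
    CofactorSpec("biotin", {"PYC1": 1}),
    CofactorSpec("heme_a", {"COX1": 2}),
]

#: per-reaction enzyme kcats (1/s) of the toy network.  Calibrated once so the
#: enzyme pool makes oxidative phosphorylation protein-expensive relative to
#: fermentation: the pool then binds near mu ~ 0.26 (onset of overflow) and
#: caps fermentative growth near mu ~ 0.42, the qualitative chemostat
#: physiology of Crabtree-positive yeast.
TOY_KCATS_PER_S = {
    "GLYCOLYSIS": ("GLY1", 1.0),
    "PDC": ("PDC1", 20.0),
    "ADH": ("ADH1", 100.0),
    "ALD": ("ALD1", 2.0),
    "GLYCEROL_SYN": ("GPD1", 20.0),
    "PYR_SYN": ("ACS1", 10.0),
    "GNG": ("FBP1", 10.0),
    "PYR_OX": ("PDA1", 10.0),
    "SDH": ("SDH1", 10.0),
    "FUM_MDH": ("FUM1", 20.0),
    "NDI": ("NDI1", 20.0),
    "NDE": ("NDE1", 20.0),
    "CIII": ("QCR2", 5.0),
    "CIV": ("COX1", 5.0),
    "ATPS": ("ATP1", 1.0),
    "ANT": ("AAC1", 70.9),
    "PIC": ("PIC1", 70.9),
    "PYRT_MITO": ("PYRC", 70.9),
    "PYC": ("PYC1", 10.0),
    "PYRt_pm": ("JEN1", 1.0),
}
RIBOSOME_KCAT_PER_H = 1250.0  # g pool per mmol ribosome per h (lumped translation)


# ---------------------------------------------------------------------------
# the toy model
# ---------------------------------------------------------------------------

def generate_toy_model(seed: int = 0, gaec: float = DEFAULT_GAEC,
                       ngam: float = DEFAULT_NGAM):
    """Build the toy yeast core network; returns ``(Model, FixtureManifest)``.

    The emitted model is purely stoichiometric (with enzyme/kcat annotations
    on the reactions); PMF coupling, import reactions, cofactor layers and
    enzyme constraints are applied by their respective modules.
    """
    rng = np.random.default_rng(seed)
    m = Model(id=f"ecmito_toy_seed{seed}")
    for cid, name, kind in [
        ("e", "extracellular", "extracellular"),
        ("c", "cytosol", "cytosol"),
        ("mom", "mitochondrial outer membrane", "mito_outer_membrane"),
        ("ims", "mitochondrial intermembrane space", "mito_intermembrane_space"),
        ("mim", "mitochondrial inner membrane", "mito_inner_membrane"),
        ("mm", "mitochondrial matrix", "mito_matrix"),
        ("pseudo", "pseudo entities", "pseudo"),
    ]:
        m.add_compartment(Compartment(cid, name, kind))

    def met(mid, comp, charge, formula=None, name="", pseudo=False):
        m.add_metabolite(Metabolite(mid, name or mid, comp, charge, formula, pseudo))

    atp, adp = "C10H12N5O13P3", "C10H12N5O10P2"
    nad, nadh = "C21H26N7O14P2", "C21H27N7O14P2"
    for comp in ("c", "ims", "mm"):
        met(f"atp_{comp}", comp, -4, atp, "ATP")
        met(f"adp_{comp}", comp, -3, adp, "ADP")
        met(f"h2po4_{comp}", comp, -1, "H2O4P", "phosphate")
    for comp in ("c", "mm"):
        met(f"nad_{comp}", comp, -1, nad, "NAD+")
        met(f"nadh_{comp}", comp, -2, nadh, "NADH")
    met("nadp_mm", "mm", -3, "C21H25N7O17P3", "NADP+")
    met("nadph_mm", "mm", -4, "C21H26N7O17P3", "NADPH")
    for comp in ("e", "c", "ims", "mm"):
        met(f"h_{comp}", comp, 1, "H", "proton")
    for comp in ("e", "c", "mm"):
        met(f"h2o_{comp}", comp, 0, "H2O", "water")
        met(f"o2_{comp}", comp, 0, "O2", "oxygen")
        met(f"co2_{comp}", comp, 0, "CO2", "carbon dioxide")
    met("glc_e", "e", 0, "C6H12O6", "glucose"); met("glc_c", "c", 0, "C6H12O6", "glucose")
    for comp in ("e", "c", "ims", "mm"):
        met(f"pyr_{comp}", comp, -1, "C3H3O3", "pyruvate")
    met("etoh_e", "e", 0, "C2H6O", "ethanol"); met("etoh_c", "c", 0, "C2H6O", "ethanol")
    met("acald_c", "c", 0, "C2H4O", "acetaldehyde")
    met("ac_e", "e", -1, "C2H3O2", "acetate"); met("ac_c", "c", -1, "C2H3O2", "acetate")
    met("glyc_e", "e", 0, "C3H8O3", "glycerol"); met("glyc_c", "c", 0, "C3H8O3", "glycerol")
    met("nh4_e", "e", 1, "H4N", "ammonium"); met("nh4_c", "c", 1, "H4N", "ammonium")
    met("succ_mm", "mm", -2, "C4H4O4", "succinate")
    met("fum_mm", "mm", -2, "C4H2O4", "fumarate")
    met("oaa_mm", "mm", -2, "C4H2O5", "oxaloacetate")
    met("q_mim", "mim", 0, "C39H58O4", "ubiquinone-6")
    met("qh2_mim", "mim", 0, "C39H60O4", "ubiquinol-6")
    met("cytc_ox_ims", "ims", 3, None, "cytochrome c (oxidized)")
    met("cytc_red_ims", "ims", 2, None, "cytochrome c (reduced)")
    for comp in ("e", "c", "ims", "mm"):
        met(f"fe2_{comp}", comp, 2, "Fe", "ferrous iron")
    met("cys_e", "e", 0, "C3H7NO2S", "cysteine"); met("cys_c", "c", 0, "C3H7NO2S", "cysteine")
    met("cys_mm", "mm", 0, "C3H7NO2S", "cysteine")
    met("ala_c", "c", 0, "C3H7NO2", "alanine"); met("ala_mm", "mm", 0, "C3H7NO2", "alanine")
    met("ala_e", "e", 0, "C3H7NO2", "alanine")
    for mid in ("lipoate_mm", "biotin_mm", "heme_a_mm"):
        met(mid, "mm", 0, None, mid.replace("_mm", "").replace("_", " "))
    for mid in ("protein_pool_c", "carb_pool_c", "lipid_pool_c", "biomass_c"):
        met(mid, "c", 0, None, mid)

    proteins = _toy_proteins(rng)
    for record in proteins.values():
        m.add_protein(record)

    def rxn(rid, stoich, lb=0.0, ub=1000.0, name="", subsystem="", exchange=False,
            transport=False, biomass=False, ann=None):
        enzymes = []
        if rid in TOY_KCATS_PER_S:
            pid, kcat_s = TOY_KCATS_PER_S[rid]
            enzymes = [(pid, kcat_s * H)]
        m.add_reaction(Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            enzymes=enzymes, subsystem=subsystem, name=name, is_exchange=exchange,
            is_transport=transport, is_biomass=biomass, annotations=ann or {},
        ))

    big = 1000.0
    # exchanges (uptake = negative flux)
    rxn("EX_glc", {"glc_e": -1}, -10, 0, "glucose exchange", exchange=True)
    rxn("EX_o2", {"o2_e": -1}, -big, 0, "oxygen exchange", exchange=True,
        ann={"essential_exchange": True})
    rxn("EX_co2", {"co2_e": -1}, 0, big, "CO2 exchange", exchange=True)
    rxn("EX_etoh", {"etoh_e": -1}, 0, big, "ethanol exchange", exchange=True)
    rxn("EX_ac", {"ac_e": -1}, 0, big, "acetate exchange", exchange=True)
    rxn("EX_glyc", {"glyc_e": -1}, 0, big, "glycerol exchange", exchange=True)
    rxn("EX_pyr", {"pyr_e": -1}, 0, big, "pyruvate exchange", exchange=True)
    rxn("EX_nh4", {"nh4_e": -1}, -big, 0, "ammonium exchange", exchange=True)
    rxn("EX_h", {"h_e": -1}, -big, big, "proton exchange", exchange=True,
        ann={"essential_exchange": True})
    rxn("EX_h2o", {"h2o_e": -1}, -big, big, "water exchange", exchange=True,
        ann={"essential_exchange": True})
    rxn("EX_fe2", {"fe2_e": -1}, -big, 0, "iron(II) exchange", exchange=True)
    rxn("EX_cys", {"cys_e": -1}, -big, 0, "cysteine exchange", exchange=True)
    rxn("EX_ala", {"ala_e": -1}, 0, big, "alanine exchange", exchange=True)
    rxn("SUPPLY_LIPOATE", {"lipoate_mm": -1}, -big, 0, "lipoate supply (toy boundary)",
        exchange=True)
    rxn("SUPPLY_BIOTIN", {"biotin_mm": -1}, -big, 0, "biotin supply (toy boundary)",
        exchange=True)
    rxn("SUPPLY_HEME_A", {"heme_a_mm": -1}, -big, 0, "heme a supply (toy boundary)",
        exchange=True)
    rxn("DM_biomass", {"biomass_c": -1}, 0, big, "biomass drain", exchange=True)
    # matrix proton buffer: crossing energetics live on the PMF pseudo-metabolite,
    # so compartmental H+ is not a conserved pool
    rxn("H_BUFFER_mm", {"h_mm": -1}, -big, big, "matrix proton buffer", exchange=True)

    # plasma membrane and porin transport (no PMF coupling across these)
    rxn("GLCt", {"glc_e": -1, "glc_c": 1}, 0, big, transport=True)
    rxn("NH4t", {"nh4_e": -1, "nh4_c": 1}, 0, big, transport=True)
    rxn("ETOHt", {"etoh_c": -1, "etoh_e": 1}, -big, big, transport=True)
    rxn("ACt", {"ac_c": -1, "h_c": -1, "ac_e": 1, "h_e": 1}, 0, big, transport=True)
    rxn("GLYCt", {"glyc_c": -1, "glyc_e": 1}, 0, big, transport=True)
    rxn("PYRt_pm", {"pyr_c": -1, "h_c": -1, "pyr_e": 1, "h_e": 1}, 0, big, transport=True)
    rxn("FE2t_pm", {"fe2_e": -1, "fe2_c": 1}, 0, big, transport=True)
    rxn("CYSt_pm", {"cys_e": -1, "cys_c": 1}, 0, big, transport=True)
    rxn("ALAt_pm", {"ala_c": -1, "ala_e": 1}, 0, big, transport=True)
    rxn("Ht_pm", {"h_e": -1, "h_c": 1}, -big, big, transport=True)
    for sp in ("o2", "h2o", "co2"):
        rxn(f"{sp.upper()}t_pm", {f"{sp}_e": -1, f"{sp}_c": 1}, -big, big, transport=True)
        rxn(f"{sp.upper()}t_mito", {f"{sp}_c": -1, f"{sp}_mm": 1}, -big, big, transport=True)
    for sp in ("pyr", "atp", "adp", "h2po4", "fe2", "h"):
        rxn(f"PORIN_{sp}", {f"{sp}_c": -1, f"{sp}_ims": 1}, -big, big, transport=True)
    rxn("CYSt_mito", {"cys_c": -1, "cys_mm": 1}, 0, big, transport=True)
    rxn("ALAt_mito", {"ala_mm": -1, "ala_c": 1}, 0, big, transport=True)

    # inner-membrane carriers (classified and PMF-coupled by the pmf module)
    rxn("ANT", {"atp_mm": -1, "adp_ims": -1, "adp_mm": 1, "atp_ims": 1}, 0, big,
        "ADP/ATP translocase", transport=True)
    rxn("PIC", {"h2po4_ims": -1, "h_ims": -1, "h2po4_mm": 1, "h_mm": 1}, 0, big,
        "phosphate/H+ symporter", transport=True)
    rxn("PYRT_MITO", {"pyr_ims": -1, "h_ims": -1, "pyr_mm": 1, "h_mm": 1}, 0, big,
        "pyruvate/H+ symporter", transport=True)
    rxn("MITOFERRIN", {"fe2_ims": -1, "fe2_mm": 1}, 0, big,
        "iron(II) uniport (Delta-psi driven)", transport=True)

    # central carbon metabolism (lumped, mass and charge balanced)
    rxn("GLYCOLYSIS",
        {"glc_c": -1, "nad_c": -2, "adp_c": -2, "h2po4_c": -2,
         "pyr_c": 2, "nadh_c": 2, "atp_c": 2, "h2o_c": 2, "h_c": 4},
        0, big, "glycolysis (lumped)", "glycolysis")
    rxn("PDC", {"pyr_c": -1, "h_c": -1, "acald_c": 1, "co2_c": 1}, 0, big,
        "pyruvate decarboxylase", "fermentation")
    rxn("ADH", {"acald_c": -1, "nadh_c": -1, "h_c": -1, "etoh_c": 1, "nad_c": 1},
        -big, big, "alcohol dehydrogenase", "fermentation")
    rxn("ALD", {"acald_c": -1, "nad_c": -1, "h2o_c": -1, "ac_c": 1, "nadh_c": 1, "h_c": 2},
        0, big, "acetaldehyde dehydrogenase", "fermentation")
    rxn("GLYCEROL_SYN",
        {"glc_c": -0.5, "nadh_c": -1, "h_c": -1, "glyc_c": 1, "nad_c": 1},
        0, big, "glycerol branch (lumped)", "fermentation")
    rxn("PYR_SYN",
        {"ac_c": -1, "co2_c": -1, "nadh_c": -1, "h_c": -1, "atp_c": -1,
         "pyr_c": 1, "nad_c": 1, "adp_c": 1, "h2po4_c": 1},
        0, big, "acetate assimilation to pyruvate (lumped)", "anaplerosis")
    rxn("GNG",
        {"pyr_c": -2, "nadh_c": -2, "atp_c": -4, "h2o_c": -4, "h_c": -4,
         "glc_c": 1, "nad_c": 2, "adp_c": 4, "h2po4_c": 4},
        0, big, "gluconeogenesis (lumped)", "anaplerosis")
    rxn("PYR_OX",
        {"pyr_mm": -1, "oaa_mm": -1, "nad_mm": -3, "h2o_mm": -2,
         "succ_mm": 1, "nadh_mm": 3, "co2_mm": 3, "h_mm": 2},
        0, big, "pyruvate dehydrogenase + TCA to succinate (lumped)", "tca")
    rxn("FUM_MDH",
        {"fum_mm": -1, "h2o_mm": -1, "nad_mm": -1, "oaa_mm": 1, "nadh_mm": 1, "h_mm": 1},
        0, big, "fumarase + malate dehydrogenase (lumped)", "tca")
    rxn("PYC",
        {"pyr_mm": -1, "co2_mm": -1, "atp_mm": -1, "h2o_mm": -1,
         "oaa_mm": 1, "adp_mm": 1, "h2po4_mm": 1, "h_mm": 1},
        0, big, "pyruvate carboxylase (biotin)", "anaplerosis")
    rxn("NADPH_REGEN", {"nadh_mm": -1, "nadp_mm": -1, "nad_mm": 1, "nadph_mm": 1},
        0, big, "matrix NADPH regeneration (lumped)", "redox")

    # respiratory chain and oxidative phosphorylation
    rxn("NDE", {"nadh_c": -1, "h_c": -1, "q_mim": -1, "nad_c": 1, "qh2_mim": 1},
        0, big, "external NADH dehydrogenase (no pumping)", "oxphos",
        ann={"electron_pair_entry": True})
    rxn("NDI", {"nadh_mm": -1, "h_mm": -1, "q_mim": -1, "nad_mm": 1, "qh2_mim": 1},
        0, big, "internal NADH dehydrogenase (no pumping)", "oxphos",
        ann={"electron_pair_entry": True})
    rxn("SDH", {"succ_mm": -1, "q_mim": -1, "fum_mm": 1, "qh2_mim": 1},
        0, big, "succinate dehydrogenase ([2Fe-2S])", "oxphos",
        ann={"electron_pair_entry": True})
    rxn("CIII", {"qh2_mim": -1, "cytc_ox_ims": -2, "q_mim": 1, "cytc_red_ims": 2, "h_ims": 2},
        0, big, "complex III", "oxphos", ann={"etc_pmf_per_unit": 4.0})
    rxn("CIV", {"cytc_red_ims": -2, "o2_mm": -0.5, "h_ims": -2, "cytc_ox_ims": 2, "h2o_mm": 1},
        0, big, "complex IV (heme a)", "oxphos", ann={"etc_pmf_per_unit": 2.0})
    rxn("ATPS", {"adp_mm": -1, "h2po4_mm": -1, "atp_mm": 1, "h2o_mm": 1},
        0, big, "ATP synthase", "oxphos", ann={"atp_synthase": True})

    # biomass, polymerization and maintenance
    rxn("PROT_SYN",
        {"glc_c": -7.5, "nh4_c": -9, "atp_c": -4, "h2o_c": -4,
         "protein_pool_c": 1, "adp_c": 4, "h2po4_c": 4, "h_c": 9},
        0, big, "protein synthesis (4 ATP/g polymerization)", "biomass")
    m.reactions["PROT_SYN"].enzymes = [("RIB1", RIBOSOME_KCAT_PER_H)]
    rxn("CARB_SYN",
        {"glc_c": -6.2, "atp_c": -1, "h2o_c": -1,
         "carb_pool_c": 1, "adp_c": 1, "h2po4_c": 1},
        0, big, "carbohydrate synthesis (1 ATP/g)", "biomass")
    rxn("LIPID_SYN",
        {"glc_c": -3, "atp_c": -1, "h2o_c": -1,
         "lipid_pool_c": 1, "adp_c": 1, "h2po4_c": 1},
        0, big, "lipid synthesis (1 ATP/g)", "biomass")
    rxn("BIOMASS",
        {**{mid: -frac for mid, frac in BIOMASS_COMPOSITION.items()},
         "atp_c": -gaec, "h2o_c": -gaec, "biomass_c": 1, "adp_c": gaec, "h2po4_c": gaec},
        0, big, "biomass (growth rate, 1/h)", "biomass", biomass=True,
        ann={"macromolecule_pools": list(BIOMASS_COMPOSITION)})
    rxn("NGAM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "h2po4_c": 1},
        ngam, ngam, "non-growth maintenance", "maintenance")
    rxn("ATP_DEMAND", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "h2po4_c": 1},
        0, 0, "ATP hydrolysis demand (assays)", "maintenance")

    m.annotations["gaec_fitted"] = gaec
    m.annotations["ngam"] = ngam

    manifest = FixtureManifest(
        seed=seed,
        reaction_count=len(m.reactions),
        metabolite_count=len(m.metabolites),
        protein_count=len(m.proteins),
        polymerization_atp=sum(
            BIOMASS_COMPOSITION[p] * POLYMERIZATION_ATP[p] for p in BIOMASS_COMPOSITION
        ),
        gaec=gaec,
        ngam=ngam,
        notes=[
            "ETC pinned at 4+2 PMF per electron pair so max P/O = 6/4 = 1.5",
            "biomass polymerization cost is a round per-pool value for GAEC decomposition",
        ],
    )
    return m, manifest


# ---------------------------------------------------------------------------
# layered fixture: PMF + import + cofactors + enzyme constraints
# ---------------------------------------------------------------------------

def toy_machinery(model: Model, kcat_overrides=None) -> dict:
    """Import machinery components of the toy model with curated rates."""
    substrates_by_component: dict = {k: [] for k in
                                     ("TOM", "TIM23", "PAM", "MPP", "TIM22", "MIA", "OXA",
                                      "SMALL_TIM")}
    lengths = []
    from .protein_import import PATHWAY_MACHINERY

    for record in model.proteins.values():
        if record.annotations.get("machinery_component") or not record.sequence:
            continue
        lengths.append(len(record.sequence))
        try:
            pathway = assign_import_pathway(record)
        except Exception:
            continue
        for component in PATHWAY_MACHINERY[pathway]:
            substrates_by_component[component].append(record.id)
    median_length = float(np.median(lengths))
    kcats = curated_kcat_table(median_length, kcat_overrides)
    out = {}
    for cid, substrates in substrates_by_component.items():
        record = model.proteins[cid]
        out[cid] = ImportMachineryComponent(
            id=cid, subunits=list(record.annotations.get("subunits", [])),
            kcat=kcats[cid], substrates=substrates,
        )
    return out


def build_full_toy(seed: int = 0, pool: EnzymePool = None, pmf_spec: PMFSpec = None,
                   gaec: float = DEFAULT_GAEC):
    """Toy model with every layer applied, ready for simulation protocols.

    Order: PMF coupling -> PMF sink -> import reactions -> Fe/S pathway ->
    cofactor incorporation -> enzyme constraints -> shared pool.
    Returns ``(Model, FixtureManifest)``.
    """
    pmf_spec = pmf_spec or PMFSpec()
    pool = pool or EnzymePool()
    model, manifest = generate_toy_model(seed, gaec=gaec)
    model = apply_pmf_coupling(model, pmf_spec)
    model = add_pmf_sink(model, pmf_spec)
    model = integrate_import(model, toy_machinery(model), pmf_spec)
    stages = build_fes_pathway(
        {"NFS1": "NFS1", "ISU": "ISU1", "FES_TRANSFER": "SSQ1", "ISA": "ISA1"},
        {"NFS1": 5.0 * H, "ISU1": 2.0 * H, "SSQ1": 2.0 * H, "ISA1": 2.0 * H},
    )
    model = add_fes_pathway(model, stages)
    model = add_cofactor_incorporation(model, TOY_COFACTOR_SPECS)
    model = apply_enzyme_constraints(model)
    model = apply_pool_constraint(model, pool)
    manifest.reaction_count = len(model.reactions)
    manifest.metabolite_count = len(model.metabolites)
    return model, manifest


# ---------------------------------------------------------------------------
# synthetic proteome / proteomics / exchange data
# ---------------------------------------------------------------------------

_SUBSTRATE_ARCHETYPES = (
    # (compartment, preseq, n_tm, proline, motif, carrier)
    ("mito_matrix", 20, 0, False, None, False),
    ("mito_inner_membrane", 18, 1, False, None, False),
    ("mito_inner_membrane", 18, 1, True, None, False),
    ("mito_inner_membrane", 0, 3, False, None, True),
    ("mito_intermembrane_space", 0, 0, False, "twin-CX9C", False),
    ("mito_outer_membrane", 0, 0, False, None, False),
)


def generate_synthetic_proteome(seed: int, n_proteins: int = 20) -> pd.DataFrame:
    """Synthetic mitochondrial protein table spanning all import pathways.

    The first eight records are one machinery subunit per translocation
    machine; the rest cycle through pathway archetypes with sequence
    compositions chosen so import PMF costs span roughly 0-10.
    """
    if n_proteins < 8:
        raise ValueError("need at least 8 proteins (one per machinery component)")
    rng = np.random.default_rng(seed)
    records = []

    machinery_specs = [
        ("sTOM40", "mito_outer_membrane", 0, 0, False, None, False),
        ("sTIM23", "mito_inner_membrane", 18, 2, False, None, False),
        ("sPAM18", "mito_matrix", 16, 0, False, None, False),
        ("sMPP1", "mito_matrix", 18, 0, False, None, False),
        ("sTIM22", "mito_inner_membrane", 0, 3, False, None, True),
        ("sMIA40", "mito_intermembrane_space", 0, 0, False, "twin-CX9C", False),
        ("sOXA1", "mito_inner_membrane", 20, 1, True, None, False),
        ("sTIM10", "mito_intermembrane_space", 0, 0, False, "twin-CX9C", False),
    ]
    for pid, comp, pre_len, n_tm, proline, motif, carrier in machinery_specs:
        records.append(_make_record(rng, pid, comp, pre_len, n_tm, proline, motif,
                                    carrier, extra_kr=6, extra_de=4))
    for i in range(n_proteins - 8):
        comp, pre_len, n_tm, proline, motif, carrier = _SUBSTRATE_ARCHETYPES[
            i % len(_SUBSTRATE_ARCHETYPES)
        ]
        # sweep charge compositions so PMF costs cover 0 .. ~10
        extra_kr = 2 * (i % 7)
        extra_de = 2 if i % 7 else 2 * (i % 3) + 2  # includes net-neutral/negative cases
        records.append(_make_record(rng, f"SUB{i:03d}", comp, pre_len, n_tm, proline,
                                    motif, carrier, extra_kr=extra_kr, extra_de=extra_de))
    return proteome_table(records)


def _make_record(rng, pid, comp, pre_len, n_tm, proline, motif, carrier,
                 extra_kr, extra_de) -> ProteinRecord:
    length = int(rng.integers(100, 450))
    pre = _presequence(rng, pre_len) if pre_len else ""
    body = _body(rng, length, extra_kr=extra_kr, extra_de=extra_de)
    segments = []
    if n_tm:
        body, segments = _with_tm(rng, body, n_tm, proline=proline)
        segments = [(s + len(pre), e + len(pre)) for s, e in segments]
    seq = pre + body
    return ProteinRecord(
        id=pid, sequence=seq, mw=sequence_mw(seq), compartment=comp,
        presequence_length=len(pre), tm_segments=segments,
        cysteine_motif=motif, is_carrier=carrier,
    )


def proteome_table(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "sequence": r.sequence,
            "mw": round(r.mw, 5),
            "compartment": r.compartment,
            "presequence_length": r.presequence_length,
            "tm_segments": ";".join(f"{s}-{e}" for s, e in r.tm_segments),
            "motif": r.cysteine_motif or "",
            "is_carrier": r.is_carrier,
        })
    return pd.DataFrame(rows)


def records_from_table(table: pd.DataFrame) -> dict:
    out = {}
    for _, row in table.iterrows():
        segments = []
        if isinstance(row["tm_segments"], str) and row["tm_segments"]:
            for part in row["tm_segments"].split(";"):
                s, e = part.split("-")
                segments.append((int(s), int(e)))
        out[row["id"]] = ProteinRecord(
            id=row["id"], sequence=row["sequence"], mw=float(row["mw"]),
            compartment=row["compartment"],
            presequence_length=int(row["presequence_length"]),
            tm_segments=segments, cysteine_motif=(row["motif"] or None),
            is_carrier=bool(row["is_carrier"]),
        )
    return out


def machinery_from_proteome(records: dict, kcats: dict) -> dict:
    """Machinery components (one subunit each) over a synthetic proteome."""
    from .protein_import import PATHWAY_MACHINERY

    subunit_of = {
        "TOM": "sTOM40", "TIM23": "sTIM23", "PAM": "sPAM18", "MPP": "sMPP1",
        "TIM22": "sTIM22", "MIA": "sMIA40", "OXA": "sOXA1", "SMALL_TIM": "sTIM10",
    }
    machinery_ids = set(subunit_of.values())
    substrates: dict = {k: [] for k in subunit_of}
    for record in records.values():
        if record.id in machinery_ids:
            # machinery subunits are not booked as their own substrates; their
            # levels are set by the substrate load they carry
            continue
        pathway = assign_import_pathway(record)
        for component in PATHWAY_MACHINERY[pathway]:
            substrates[component].append(record.id)
    return {
        cid: ImportMachineryComponent(
            id=cid, subunits=[subunit_of[cid]], kcat=kcats.get(cid, 10.0 * H),
            substrates=substrates[cid],
        )
        for cid in subunit_of
    }


def generate_synthetic_proteomics(
    proteome: pd.DataFrame,
    mu: float,
    kcats: dict,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Absolute abundances (mmol/gDW) consistent with the import steady state.

    Substrate abundances are drawn lognormally around 1e-5 mmol/gDW; each
    machinery subunit gets abundance mu * sum(substrates) / kcat, the level
    needed to re-import the standing substrate pool every doubling.  Lognormal
    noise of the stated CV is applied multiplicatively.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    records = records_from_table(proteome)
    machinery = machinery_from_proteome(records, kcats)
    machinery_subunits = {c.subunits[0]: c for c in machinery.values()}

    sigma_ln = float(np.sqrt(np.log(1.0 + noise_cv ** 2)))

    def noisy(x: float) -> float:
        if noise_cv == 0:
            return x
        return x * float(rng.lognormal(-0.5 * sigma_ln ** 2, sigma_ln))

    base = {}
    for pid in records:
        if pid in machinery_subunits:
            continue
        base[pid] = float(rng.lognormal(np.log(1e-5), 0.5))
    rows = [{"protein_id": pid, "abundance": noisy(x)} for pid, x in base.items()]
    for pid, component in machinery_subunits.items():
        total = sum(base.get(s, 0.0) for s in component.substrates)
        level = mu * total / component.kcat if component.kcat > 0 else 0.0
        rows.append({"protein_id": pid, "abundance": noisy(level)})

    table = pd.DataFrame(rows)
    mass = sum(records[r.protein_id].mw * r.abundance for r in table.itertuples()
               if r.protein_id in records)
    assert mass <= EnzymePool().bound, "synthetic proteome exceeds the pool budget"
    return table


def generate_exchange_dataset(
    model: Model,
    gaec: float,
    sigma: float,
    mus,
    seed: int = 0,
    noise_cv: float = 0.0,
):
    """Chemostat exchange-flux table generated from the model itself.

    Runs the chemostat protocol at each dilution rate with the stated GAEC
    and saturation, records the exchange fluxes the dataset columns expect,
    and perturbs them with lognormal noise of the given CV.  Infeasible
    dilution rates are dropped with a warning.
    """
    from .ec_constraints import set_sigma
    from .simulate import (DATASET_EXCHANGES, ExchangeDataset, SimulationError,
                           set_biomass_gaec, simulate_chemostat)

    rng = np.random.default_rng(seed)
    work = set_biomass_gaec(model, gaec)
    if work.annotations.get("enzyme_pool"):
        work = set_sigma(work, sigma)
    sigma_ln = float(np.sqrt(np.log(1.0 + noise_cv ** 2))) if noise_cv else 0.0
    rows = []
    for mu in mus:
        try:
            result = simulate_chemostat(work, float(mu))
        except SimulationError:
            import logging

            logging.getLogger(__name__).warning("mu=%s infeasible; dropped", mu)
            continue
        row = {"mu": float(mu)}
        for col, (rid, sign) in DATASET_EXCHANGES.items():
            value = sign * result.fluxes.get(rid, 0.0)
            if noise_cv and value > 1e-9:
                value *= float(rng.lognormal(-0.5 * sigma_ln ** 2, sigma_ln))
            row[col] = value
        rows.append(row)
    return ExchangeDataset(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# on-disk fixture bundles
# ---------------------------------------------------------------------------

def write_fixture_bundle(out_dir, seed: int = 0) -> dict:
    """Write model JSON/SBML, proteome, kcat and abundance TSVs to a directory."""
    from pathlib import Path

    from .io import write_model

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, manifest = generate_toy_model(seed)
    write_model(model, out / "toy_model.json")
    write_model(model, out / "toy_model.xml", format="sbml")
    proteome = generate_synthetic_proteome(seed)
    proteome.to_csv(out / "proteome.tsv", sep="\t", index=False)
    kcat_rows = [
        {"protein_id": pid, "reaction_id": rid, "kcat_per_s": kcat_s}
        for rid, (pid, kcat_s) in TOY_KCATS_PER_S.items()
    ]
    pd.DataFrame(kcat_rows).to_csv(out / "kcats.tsv", sep="\t", index=False)
    abundances = generate_synthetic_proteomics(
        proteome, mu=0.1, kcats=curated_kcat_table(375.0), seed=seed
    )
    abundances.to_csv(out / "proteomics.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))
    return manifest.to_dict()
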