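"""Import pathway assignment, energetics and turnover estimation."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecmito import (
    assign_import_pathway,
    build_import_reactions,
    compute_import_pmf_cost,
    compute_matrix_import_atp_cost,
    curated_kcat_table,
    estimate_import_kcat,
    impute_protein_abundance,
)
from ecmito.model_core import ProteinRecord
from ecmito.protein_import import (
    ImportAssignment,
    ImportMachineryComponent,
    UnassignableProteinError,
    make_assignment,
    net_positive_charge,
)


def record(seq="MAAAAAAAAA", compartment="mito_matrix", preseq=0, tm=None,
           motif=None, carrier=False):
    return ProteinRecord(
        id="P1", sequence=seq, mw=len(seq) * 0.11, compartment=compartment,
        presequence_length=preseq, tm_segments=tm or [], cysteine_motif=motif,
        is_carrier=carrier,
    )


class TestPathwayAssignment:
    def test_proline_in_tm_means_conservative_sorting(self):
        # TM segment "LAPLLVI" contains a proline
        protein = record("MKRS" + "LAPLLVI" + "AAAA", "mito_inner_membrane",
                         preseq=4, tm=[(5, 11)])
        assert assign_import_pathway(protein) == "TIM23_conservative_sorting"

    def test_proline_free_tm_means_stop_transfer(self):
        protein = record("MKRS" + "LLAVLLI" + "AAAA", "mito_inner_membrane",
                         preseq=4, tm=[(5, 11)])
        assert assign_import_pathway(protein) == "TIM23_stop_transfer"

    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(compartment="mito_matrix", preseq=8), "TIM23_matrix"),
            (dict(compartment="mito_outer_membrane"), "TOM_only"),
            (dict(compartment="mito_intermembrane_space", motif="twin-CX9C"), "MIA"),
            (dict(compartment="mito_inner_membrane", carrier=True), "TIM22_carrier"),
        ],
    )
    def test_definitional_pathways(self, kwargs, expected):
        assert assign_import_pathway(record(**kwargs)) == expected

    def test_ims_protein_without_motif_or_presequence_unassignable(self):
        with pytest.raises(UnassignableProteinError):
            assign_import_pathway(record(compartment="mito_intermembrane_space"))

    def test_cytosolic_protein_unassignable(self):
        with pytest.raises(UnassignableProteinError):
            assign_import_pathway(record(compartment="cytosol"))


class TestATPCost:
    @pytest.mark.parametrize("length, expected", [(25, 1), (375, 15), (0, 0), (26, 2), (50, 2)])
    def test_one_atp_per_25_residues(self, length, expected):
        assert compute_matrix_import_atp_cost(length) == expected

    def test_negative_length_raises(self):
        with pytest.raises(ValueError):
            compute_matrix_import_atp_cost(-1)

    def test_linear_mode(self):
        assert compute_matrix_import_atp_cost(30, rounding="linear") == pytest.approx(1.2)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 5000), st.integers(0, 500))
    def test_monotone_in_length(self, length, delta):
        assert (compute_matrix_import_atp_cost(length + delta)
                >= compute_matrix_import_atp_cost(length))


class TestPMFCost:
    def test_net_positive_charge_scales_cost(self):
        # 7 K/R against 2 D/E -> net +5 -> 4.5 PMF at the 0.9 split
        protein = record("KKKKRRRDE" + "A" * 20, preseq=0)
        assert compute_import_pmf_cost(protein, pathway="TIM23_matrix") == pytest.approx(4.5)

    def test_neutral_region_costs_nothing(self):
        protein = record("KRDE" + "A" * 20)
        assert compute_import_pmf_cost(protein, pathway="TIM23_matrix") == 0.0

    def test_net_negative_region_floors_at_zero(self):
        protein = record("DDEE" + "A" * 20)
        assert compute_import_pmf_cost(protein, pathway="TIM23_matrix") == 0.0

    def test_stop_transfer_charges_presequence_only(self):
        seq = "KKKK" + "DDDD" + "A" * 20
        protein = record(seq, "mito_inner_membrane", preseq=4, tm=[(9, 14)])
        assert compute_import_pmf_cost(protein, pathway="TIM23_stop_transfer") \
            == pytest.approx(4 * 0.9)

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=200))
    def test_charge_floor_property(self, region):
        assert net_positive_charge(region) >= 0
        assert net_positive_charge(region + "K") >= net_positive_charge(region)


class TestImportReactions:
    MACHINERY = {
        cid: ImportMachineryComponent(id=cid, kcat=36000.0)
        for cid in ("TOM", "TIM23", "PAM", "MPP", "TIM22", "MIA", "OXA", "SMALL_TIM")
    }

    def test_matrix_import_reaction_stoichiometry(self):
        # 50 residues -> 2 ATP; net +3 imported charge -> 2.7 PMF
        seq = "KKKR" + "D" + "A" * 45
        protein = record(seq, "mito_matrix", preseq=4)
        assignment = make_assignment(protein)
        assert assignment.atp_cost == 2 and assignment.pmf_cost == pytest.approx(2.7)
        (rxn,) = build_import_reactions(protein, assignment, self.MACHINERY)
        assert rxn.stoichiometry["atp_mm"] == -2 and rxn.stoichiometry["adp_mm"] == 2
        assert rxn.stoichiometry["h2po4_mm"] == 2
        assert rxn.stoichiometry["pmf"] == pytest.approx(-2.7)
        assert {pid for pid, _ in rxn.enzymes} == {"TOM", "TIM23", "PAM", "MPP"}
        # one protein species consumed, one produced
        assert rxn.stoichiometry["prot_P1_c"] == -1
        assert rxn.stoichiometry["prot_P1_loc"] == 1

    def test_outer_membrane_import_is_free(self):
        protein = record("M" + "A" * 99, "mito_outer_membrane")
        (rxn,) = build_import_reactions(protein, make_assignment(protein), self.MACHINERY)
        assert {pid for pid, _ in rxn.enzymes} == {"TOM"}
        assert "atp_mm" not in rxn.stoichiometry and "pmf" not in rxn.stoichiometry

    def test_mia_substrate_engages_disulfide_relay(self):
        protein = record("M" + "A" * 80, "mito_intermembrane_space", motif="twin-CX9C")
        (rxn,) = build_import_reactions(protein, make_assignment(protein), self.MACHINERY)
        assert {pid for pid, _ in rxn.enzymes} == {"TOM", "MIA"}
        assert "atp_mm" not in rxn.stoichiometry

    def test_conservative_sorting_engages_oxa(self):
        seq = "MKRS" + "LAPLLVI" + "A" * 30
        protein = record(seq, "mito_inner_membrane", preseq=4, tm=[(5, 11)])
        (rxn,) = build_import_reactions(protein, make_assignment(protein), self.MACHINERY)
        assert "OXA" in {pid for pid, _ in rxn.enzymes}

    def test_missing_machinery_raises(self):
        protein = record("M" + "A" * 50, "mito_matrix", preseq=4)
        from ecmito.protein_import import ImportConfigurationError

        with pytest.raises(ImportConfigurationError):
            build_import_reactions(protein, make_assignment(protein), {"TOM": self.MACHINERY["TOM"]})

    def test_tom_and_mia_assignments_are_atp_free_by_contract(self):
        with pytest.raises(ValueError):
            ImportAssignment("X", "TOM_only", atp_cost=1)


class TestKcatEstimation:
    def test_arithmetic(self):
        component = ImportMachineryComponent(
            id="TOM", subunits=["t1"], substrates=["a", "b"]
        )
        abundances = {"a": 1e-4, "b": 1e-4, "t1": 1e-6}
        assert estimate_import_kcat(component, abundances, 0.1) == pytest.approx(20.0)

    def test_ratio_one_returns_mu(self):
        component = ImportMachineryComponent(id="X", subunits=["s"], substrates=["a"])
        assert estimate_import_kcat(component, {"a": 5e-5, "s": 5e-5}, 0.2) \
            == pytest.approx(0.2)

    def test_empty_substrates_returns_zero(self):
        component = ImportMachineryComponent(id="X", subunits=["s"], substrates=[])
        assert estimate_import_kcat(component, {"s": 1e-6}, 0.1) == 0.0

    def test_zero_subunit_abundance_raises(self):
        component = ImportMachineryComponent(id="X", subunits=["s"], substrates=["a"])
        with pytest.raises(ZeroDivisionError):
            estimate_import_kcat(component, {"a": 1e-5, "s": 0.0}, 0.1)


class TestCuratedRates:
    def test_tom_runs_at_translation_rate(self):
        table = curated_kcat_table(375.0)
        assert table["TOM"] == pytest.approx(36000.0)
        assert table["OXA"] == pytest.approx(36000.0)

    def test_tim23_rate_scales_with_median_length(self):
        table = curated_kcat_table(375.0)
        assert table["TIM23"] == pytest.approx(9.0 / 375.0 * 3600.0)
        assert table["PAM"] == table["TIM23"]

    def test_override_wins(self):
        table = curated_kcat_table(375.0, overrides={"TOM": 123.0})
        assert table["TOM"] == 123.0

    def test_invalid_median_raises(self):
        with pytest.raises(ValueError):
            curated_kcat_table(0.0)


class TestImputation:
    def test_missing_subunit_imputed_from_complex_ratio(self):
        proteomics = pd.DataFrame(
            {"protein_id": ["a", "b"], "abundance": [100.0, 400.0]}
        )
        transcriptomics = pd.DataFrame(
            {"protein_id": ["a", "b", "c"], "abundance": [1.0, 2.0, 3.0]}
        )
        membership = {"a": "TOM", "b": "TOM", "c": "TOM"}
        out = impute_protein_abundance(proteomics, transcriptomics, membership)
        row = out.set_index("protein_id").loc["c"]
        assert row["abundance"] == pytest.approx(3.0 * 150.0)  # mean ratio (100+200)/2
        assert bool(row["imputed"])

    def test_measured_protein_unchanged(self):
        proteomics = pd.DataFrame({"protein_id": ["a"], "abundance": [7.0]})
        transcriptomics = pd.DataFrame({"protein_id": ["a"], "abundance": [2.0]})
        out = impute_protein_abundance(proteomics, transcriptomics, {"a": "X"})
        assert out.set_index("protein_id").loc["a", "abundance"] == 7.0

    def test_fully_unmeasured_complex_flagged_missing(self):
        proteomics = pd.DataFrame({"protein_id": [], "abundance": []})
        transcriptomics = pd.DataFrame({"protein_id": ["c"], "abundance": [3.0]})
        out = impute_protein_abundance(proteomics, transcriptomics, {"c": "X"})
        assert math.isnan(out.set_index("protein_id").loc["c", "abundance"])
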