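"""Structural model container, I/O round-trips and validation."""

import libsbml
import pytest

from ecmito import read_model, write_model, validate_model, assign_complex_compartment
from ecmito.io import model_to_dict
from ecmito.model_core import (
    AmbiguityError,
    Compartment,
    InfeasibleCompositionError,
    Metabolite,
    Model,
    Reaction,
    ReferenceError_,
    ValidationError,
    update_biomass_lipids,
)


class TestRoundTrip:
    def test_json_round_trip_is_identity(self, toy_model, tmp_path):
        path = tmp_path / "model.json"
        write_model(toy_model, path)
        again = read_model(path)
        assert model_to_dict(again) == model_to_dict(toy_model)

    def test_sbml_round_trip_is_identity(self, coupled_model, tmp_path):
        # the PMF pseudo-metabolite and kcat pairs must survive SBML
        path = tmp_path / "model.xml"
        write_model(coupled_model, path, format="sbml")
        again = read_model(path, format="sbml")
        assert model_to_dict(again) == model_to_dict(coupled_model)
        assert again.metabolites["pmf"].is_pseudo

    def test_sbml_output_is_valid_sbml(self, toy_model, tmp_path):
        path = tmp_path / "model.xml"
        write_model(toy_model, path, format="sbml")
        doc = libsbml.readSBMLFromFile(str(path))
        doc.checkInternalConsistency()
        assert doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) == 0

    def test_dangling_metabolite_reference_raises(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            '{"schema_version": "1", "compartments": [{"id": "c", "kind": "cytosol"}],'
            '"metabolites": [], "reactions": '
            '[{"id": "R1", "stoichiometry": {"ghost": -1.0}}]}'
        )
        with pytest.raises(ReferenceError_):
            read_model(path)

    def test_invalid_model_refused_before_write(self, toy_model, tmp_path):
        broken = toy_model.copy()
        broken.reactions["GLYCOLYSIS"].lower_bound = 5.0
        broken.reactions["GLYCOLYSIS"].upper_bound = -5.0
        with pytest.raises(ValidationError):
            write_model(broken, tmp_path / "x.json")
        assert not (tmp_path / "x.json").exists()


class TestValidation:
    def test_toy_fixture_has_zero_violations(self, toy_model):
        assert validate_model(toy_model) == []

    def test_unbalanced_reaction_is_flagged(self, toy_model):
        broken = toy_model.copy()
        # ATP -> ADP without the phosphate: element and charge imbalance
        broken.add_reaction(
            Reaction(id="BROKEN", stoichiometry={"atp_c": -1, "adp_c": 1})
        )
        problems = [v for v in validate_model(broken) if "BROKEN" in v]
        assert any("imbalance" in v for v in problems)

    def test_pmf_pseudo_metabolite_is_exempt(self, coupled_model):
        # PMF-coupled reactions carry an unbalanced pseudo-species on purpose
        assert validate_model(coupled_model) == []

    def test_manifest_counts_match_model(self, toy):
        model, manifest = toy
        assert manifest.reaction_count == len(model.reactions)
        assert manifest.metabolite_count == len(model.metabolites)
        assert manifest.protein_count == len(model.proteins)


class TestComplexCompartment:
    @pytest.mark.parametrize(
        "kinds, expected",
        [
            (["mito_matrix", "mito_inner_membrane"], "mito_inner_membrane"),
            (["mito_matrix", "mito_matrix"], "mito_matrix"),
            (["mito_intermembrane_space", "mito_outer_membrane"], "mito_outer_membrane"),
        ],
    )
    def test_membrane_wins(self, kinds, expected):
        assert assign_complex_compartment(kinds) == expected

    @pytest.mark.parametrize(
        "kinds",
        [
            ["mito_outer_membrane", "mito_inner_membrane"],  # spans both membranes
            ["mito_matrix", "mito_intermembrane_space"],     # irreconcilable soluble
            [],
            ["cytosol"],
        ],
    )
    def test_ambiguous_inputs_raise(self, kinds):
        with pytest.raises(AmbiguityError):
            assign_complex_compartment(kinds)


class TestBiomassLipids:
    def test_secondary_species_fill_residual_mass(self):
        coeff = update_biomass_lipids(
            primary_lipids={"PC": 40.0},
            secondary_lipids={"PE": 1.0},
            molecular_weights={"PC": 760.0, "PE": 700.0},
            total_lipid_fraction=0.08,
        )
        # residual 80 - 40 = 40 mg/gDW all to PE
        assert coeff["PE"] == pytest.approx(40.0 / 700.0)
        assert coeff["PC"] == pytest.approx(40.0 / 760.0)

    def test_total_mass_equals_lipid_fraction(self):
        coeff = update_biomass_lipids(
            {"PC": 25.0, "PI": 10.0},
            {"PE": 0.5, "PS": 0.3, "CL": 0.2},
            {"PC": 760.0, "PI": 860.0, "PE": 700.0, "PS": 790.0, "CL": 1400.0},
            0.08,
        )
        mass = sum(coeff[sp] * mw for sp, mw in
                   {"PC": 760.0, "PI": 860.0, "PE": 700.0, "PS": 790.0, "CL": 1400.0}.items())
        assert mass == pytest.approx(80.0, abs=1e-9)

    def test_empty_secondary_leaves_primary_unchanged(self):
        coeff = update_biomass_lipids({"PC": 40.0}, {}, {"PC": 760.0}, 0.08)
        assert coeff == {"PC": pytest.approx(40.0 / 760.0)}

    def test_primary_mass_exceeding_total_raises(self):
        with pytest.raises(InfeasibleCompositionError):
            update_biomass_lipids({"PC": 90.0}, {}, {"PC": 760.0}, 0.08)

    def test_species_in_both_tables_keeps_primary(self):
        coeff = update_biomass_lipids(
            {"PC": 40.0}, {"PC": 0.9, "PE": 0.1}, {"PC": 760.0, "PE": 700.0}, 0.08
        )
        assert coeff["PC"] == pytest.approx(40.0 / 760.0)
        assert coeff["PE"] == pytest.approx(40.0 / 700.0)  # full residual
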