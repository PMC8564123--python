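"""PMF classification, coupling, P/O ratio and accounting."""

import pytest

from ecmito import classify_translocation, compute_po_ratio, pmf_accounting
from ecmito.model_core import Metabolite, Reaction
from ecmito.pmf import (
    MissingChargeError,
    PMFMisuseError,
    PMFSpec,
    add_pmf_sink,
    apply_pmf_coupling,
)


class TestPMFSpec:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PMFSpec(delta_psi_fraction=0.8, delta_ph_fraction=0.1)

    def test_defaults(self):
        spec = PMFSpec()
        assert (spec.delta_psi_fraction, spec.delta_ph_fraction) == (0.9, 0.1)
        assert spec.synthase_pmf_per_atp == 3.0


class TestClassification:
    @pytest.mark.parametrize(
        "rid, expected_class, expected_charge, expected_protons",
        [
            ("ANT", "charge_translocating", -1.0, 0.0),
            ("PIC", "proton_coupled_electroneutral", 0.0, 1.0),
            ("PYRT_MITO", "proton_coupled_electroneutral", 0.0, 1.0),
            ("MITOFERRIN", "charge_translocating", -2.0, 0.0),
            ("O2t_mito", "neutral", 0.0, 0.0),
            ("GLYCOLYSIS", "neutral", 0.0, 0.0),   # cytosolic, not membrane-spanning
            ("NDI", "neutral", 0.0, 0.0),          # quinone pool is not a crossing
        ],
    )
    def test_decision_table(self, toy_model, rid, expected_class, expected_charge,
                            expected_protons):
        profile = classify_translocation(toy_model.reactions[rid], toy_model)
        assert profile.classification == expected_class
        assert profile.net_charge_moved == pytest.approx(expected_charge)
        assert profile.protons_moved == pytest.approx(expected_protons)

    def test_missing_charge_raises(self, toy_model):
        model = toy_model.copy()
        model.add_metabolite(Metabolite("mystery_mm", compartment="mm", charge=None))
        model.add_metabolite(Metabolite("mystery_ims", compartment="ims", charge=None))
        model.add_reaction(Reaction(
            id="MYSTERY_T", stoichiometry={"mystery_ims": -1, "mystery_mm": 1}
        ))
        with pytest.raises(MissingChargeError):
            classify_translocation(model.reactions["MYSTERY_T"], model)


class TestCoupling:
    def test_synthase_consumes_three_pmf_per_atp(self, coupled_model):
        assert coupled_model.reactions["ATPS"].stoichiometry["pmf"] == pytest.approx(-3.0)

    def test_chain_complexes_produce_tagged_pmf(self, coupled_model):
        assert coupled_model.reactions["CIII"].stoichiometry["pmf"] == pytest.approx(4.0)
        assert coupled_model.reactions["CIV"].stoichiometry["pmf"] == pytest.approx(2.0)

    def test_translocase_coefficients(self, coupled_model):
        assert coupled_model.reactions["ANT"].stoichiometry["pmf"] == pytest.approx(-0.9)
        assert coupled_model.reactions["PIC"].stoichiometry["pmf"] == pytest.approx(-0.1)

    def test_cytosolic_reaction_unchanged(self, coupled_model, toy_model):
        assert "pmf" not in coupled_model.reactions["GLYCOLYSIS"].stoichiometry
        assert (coupled_model.reactions["GLYCOLYSIS"].stoichiometry
                == toy_model.reactions["GLYCOLYSIS"].stoichiometry)

    def test_idempotent(self, coupled_model):
        from ecmito.io import model_to_dict

        again = apply_pmf_coupling(coupled_model, PMFSpec())
        assert model_to_dict(again) == model_to_dict(coupled_model)

    def test_override_wins(self, toy_model):
        model = apply_pmf_coupling(toy_model, overrides={"ANT": -0.5})
        assert model.reactions["ANT"].stoichiometry["pmf"] == pytest.approx(-0.5)

    def test_override_on_non_membrane_reaction_raises(self, toy_model):
        with pytest.raises(PMFMisuseError):
            apply_pmf_coupling(toy_model, overrides={"GLYCOLYSIS": -1.0})


class TestSink:
    def test_sink_added_once_and_idempotent(self, coupled_model):
        again = add_pmf_sink(coupled_model)
        assert "PMF_SINK" in again.reactions
        assert sum(1 for r in again.reactions if r == "PMF_SINK") == 1
        assert again.reactions["PMF_SINK"].lower_bound == 0.0

    def test_closed_sink_leaves_po_unchanged(self, oxphos_model):
        closed = oxphos_model.copy()
        closed.reactions["PMF_SINK"].upper_bound = 0.0
        po_open, _ = compute_po_ratio(oxphos_model, "EX_etoh", 1.0)
        po_closed, _ = compute_po_ratio(closed, "EX_etoh", 1.0)
        assert po_open == pytest.approx(po_closed, abs=1e-9)

    @pytest.mark.parametrize("leak", [0.0, 2.0, 4.0, 6.0, 9.0])
    def test_po_non_increasing_in_forced_leak(self, oxphos_model, leak):
        # analytic oracle: 12 PMF generated per ethanol, leak diverts `leak`
        model = oxphos_model.copy()
        model.reactions["PMF_SINK"].lower_bound = leak
        po, _ = compute_po_ratio(model, "EX_etoh", 1.0)
        assert po == pytest.approx((12.0 - leak) / 4.0 / 2.0, abs=1e-6)


class TestPORatio:
    def test_theoretical_maximum_on_restricted_fixture(self, oxphos_model):
        po, _ = compute_po_ratio(oxphos_model, "EX_etoh", 1.0)
        assert po == pytest.approx(1.5, abs=1e-6)

    def test_zero_uptake_raises(self, oxphos_model):
        with pytest.raises(ValueError):
            compute_po_ratio(oxphos_model, "EX_etoh", 0.0)

    def test_glucose_po_below_theoretical_maximum(self, coupled_model):
        # with pyruvate transport active, extra PMF drains lower the yield
        po, _ = compute_po_ratio(coupled_model, "EX_glc", 1.0)
        assert 1.0 < po < 1.5


class TestAccounting:
    def test_transport_fraction_is_quarter(self, oxphos_model):
        po, result = compute_po_ratio(oxphos_model, "EX_etoh", 1.0)
        table = pmf_accounting(result, oxphos_model)
        transport = table.set_index("category").loc["transport", "fraction"]
        assert transport == pytest.approx(0.25, abs=1e-9)

    def test_fractions_sum_to_one(self, oxphos_model):
        _, result = compute_po_ratio(oxphos_model, "EX_etoh", 1.0)
        table = pmf_accounting(result, oxphos_model)
        assert table["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_flux_through_sink(self, oxphos_model):
        from ecmito.simulate import solve

        model = oxphos_model.copy()
        model.reactions["ATP_DEMAND"].upper_bound = 0.0
        model.reactions["NGAM"].lower_bound = 0.0
        model.reactions["NGAM"].upper_bound = 0.0
        model.biomass_reaction.upper_bound = 0.0
        sub = model.reactions["EX_etoh"]
        sub.lower_bound = sub.upper_bound = -1.0
        for rxn in model.reactions.values():
            if rxn.is_exchange and rxn.id != "EX_etoh" and rxn.lower_bound < 0:
                if not rxn.annotations.get("essential_exchange"):
                    rxn.lower_bound = 0.0
        result = solve(model, "PMF_SINK", "max")
        assert result.status == "optimal"
        table = pmf_accounting(result, model).set_index("category")
        assert table.loc["sink", "fraction"] == pytest.approx(1.0, abs=1e-9)

    def test_model_without_pmf_raises(self, toy_model):
        from ecmito.simulate import SimulationResult

        with pytest.raises(PMFMisuseError):
            pmf_accounting(SimulationResult(), toy_model)
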