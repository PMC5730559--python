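import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gpdikit as g
from gpdikit.interaction import gpdi_shift, modulated_effect, perturbed_effect, slope_model_shift


def term(perp="B", victim="A", int_value=1.0, ec50_int=1.0, h_int=1.0, **kw):
    return g.GPDITerm(perp, victim, int_value=int_value, ec50_int=ec50_int,
                      h_int=h_int, **kw)


class TestShiftFactor:
    def test_zero_interaction_is_identity(self):
        assert gpdi_shift(term(int_value=0.0), 123.0) == 1.0

    def test_saturation_reaches_one_plus_int(self):
        # an INT of 3.32 scales the victim parameter to 432% at saturation
        assert gpdi_shift(term(int_value=3.32, ec50_int=0.5), 1e12) == pytest.approx(4.32)

    def test_half_maximal_at_interaction_potency(self):
        assert gpdi_shift(term(int_value=2.0, ec50_int=10.0), 10.0) == pytest.approx(2.0)

    def test_int_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            term(int_value=-1.2)

    @given(
        int_value=st.floats(-0.99, 20.0),
        ec50_int=st.floats(1e-3, 1e3),
        h_int=st.floats(0.3, 6.0),
        conc=st.floats(0.0, 1e6),
    )
    def test_factor_bounds(self, int_value, ec50_int, h_int, conc):
        f = gpdi_shift(term(int_value=int_value, ec50_int=ec50_int, h_int=h_int), conc)
        lo, hi = sorted((1.0, 1.0 + int_value))
        assert lo - 1e-12 <= f <= hi + 1e-12
        assert gpdi_shift(term(int_value=int_value, ec50_int=ec50_int, h_int=h_int), 0.0) == 1.0


class TestPerturbedEffect:
    def test_no_terms_reduces_to_single_drug(self, drug_a, drug_b):
        m = g.InteractionModel(drugs=(drug_a, drug_b))
        e = perturbed_effect(m, "A", {"A": drug_a.ec50, "B": 0.7})
        assert e == pytest.approx(0.5 * drug_a.emax)

    def test_effective_ec50_doubles_at_saturation(self):
        # INT_AB = 1 at saturating perpetrator dose doubles EC50_A
        a = g.SingleDrugPD("A", emax=1.0, ec50=3.0, hill=1.0)
        b = g.SingleDrugPD("B", emax=1.0, ec50=1.0, hill=1.0)
        m = g.InteractionModel(drugs=(a, b), terms=(term(int_value=1.0),))
        e = perturbed_effect(m, "A", {"A": 2 * a.ec50, "B": 1e12})
        assert e == pytest.approx(0.5, rel=1e-9)

    def test_emax_target_full_suppression(self, drug_a, drug_b):
        t = term(int_value=-1.0, target_param="Emax")
        m = g.InteractionModel(drugs=(drug_a, drug_b), terms=(t,), criterion="bliss")
        e = perturbed_effect(m, "A", {"A": 5.0, "B": 1e12})
        assert e == pytest.approx(0.0, abs=1e-9)

    def test_missing_victim_is_key_error(self, drug_a, drug_b):
        m = g.InteractionModel(drugs=(drug_a, drug_b))
        with pytest.raises(KeyError):
            perturbed_effect(m, "C", {"A": 1.0, "B": 1.0})

    def test_product_composition_of_two_perpetrators(self):
        a = g.SingleDrugPD("A", emax=1.0, ec50=2.0, hill=1.5)
        b = g.SingleDrugPD("B", emax=1.0, ec50=1.0, hill=1.0)
        c = g.SingleDrugPD("C", emax=1.0, ec50=1.0, hill=1.0)
        t1 = term("B", "A", int_value=1.0, ec50_int=1.0)
        t2 = term("C", "A", int_value=2.0, ec50_int=3.0)
        m = g.InteractionModel(drugs=(a, b, c), terms=(t1, t2))
        cb, cc = 4.0, 6.0
        f1 = gpdi_shift(t1, cb)
        f2 = gpdi_shift(t2, cc)
        direct = g.effect(g.SingleDrugPD("A", emax=1.0, ec50=2.0 * f1 * f2, hill=1.5), 3.0)
        assert perturbed_effect(m, "A", {"A": 3.0, "B": cb, "C": cc}) == pytest.approx(
            direct, rel=1e-12
        )

    def test_null_interaction_reduction_on_grid(self, drug_a, drug_b):
        tiers = np.array([0.0, 0.25, 1.0, 4.0])
        m = g.InteractionModel(
            drugs=(drug_a, drug_b),
            terms=(term(int_value=0.0), term("A", "B", int_value=0.0)),
        )
        for ca in tiers:
            for cb in tiers:
                assert perturbed_effect(m, "A", {"A": ca, "B": cb}) == g.effect(drug_a, ca)
                assert perturbed_effect(m, "B", {"A": ca, "B": cb}) == g.effect(drug_b, cb)


class TestPolarity:
    def _surface(self, model, criterion="bliss"):
        tiers = np.linspace(0, 8, 20)
        ca, cb = np.meshgrid(tiers, tiers, indexing="ij")
        return g.effect_surface(model, {"A": ca, "B": cb}, criterion)

    def test_both_negative_int_on_ec50_is_synergy_everywhere(self, drug_a, drug_b):
        null = g.InteractionModel(drugs=(drug_a, drug_b))
        syn = g.InteractionModel(
            drugs=(drug_a, drug_b),
            terms=(term(int_value=-0.7), term("A", "B", int_value=-0.7)),
        )
        assert np.all(self._surface(syn) >= self._surface(null) - 1e-12)

    def test_both_positive_int_on_ec50_is_antagonism_everywhere(self, drug_a, drug_b):
        null = g.InteractionModel(drugs=(drug_a, drug_b))
        ant = g.InteractionModel(
            drugs=(drug_a, drug_b),
            terms=(term(int_value=4.0), term("A", "B", int_value=4.0)),
        )
        assert np.all(self._surface(ant) <= self._surface(null) + 1e-12)

    def test_emax_placement_flips_polarity(self):
        # partial agonists so the boosted Emax stays on the Bliss scale
        a = g.SingleDrugPD("A", emax=0.4, ec50=1.0, hill=2.0)
        b = g.SingleDrugPD("B", emax=0.4, ec50=2.0, hill=1.5)
        null = g.InteractionModel(drugs=(a, b))
        on_ec50 = g.InteractionModel(drugs=(a, b), terms=(term(int_value=1.2),))
        on_emax = g.InteractionModel(
            drugs=(a, b), terms=(term(int_value=1.2, target_param="Emax"),)
        )
        base = self._surface(null)
        interior = base > 1e-6
        assert np.all(self._surface(on_ec50)[interior] <= base[interior] + 1e-12)
        assert np.all(self._surface(on_emax)[interior] >= base[interior] - 1e-12)


class TestModulation:
    def _three_drug_model(self, int_abc):
        a = g.SingleDrugPD("A", emax=1.0, ec50=2.0, hill=1.5)
        b = g.SingleDrugPD("B", emax=1.0, ec50=1.0, hill=1.0)
        c = g.SingleDrugPD("C", emax=1.0, ec50=1.0, hill=1.0)
        pair = term("B", "A", int_value=1.0, ec50_int=1.0)
        mod = g.GPDITerm(
            "C", "A", int_value=int_abc, ec50_int=5.0, target_param="INT",
            modulated_pair=("B", "A"),
        )
        return g.InteractionModel(drugs=(a, b, c), terms=(pair, mod))

    def test_zero_modulator_exposure_equals_pairwise(self):
        m = self._three_drug_model(1.0)
        conc = {"A": 1.5, "B": 2.0, "C": 0.0}
        assert modulated_effect(m, "A", conc) == pytest.approx(
            perturbed_effect(m, "A", conc), rel=1e-12
        )

    def test_full_negative_modulation_abolishes_interaction(self):
        m = self._three_drug_model(-1.0)
        conc = {"A": 1.5, "B": 2.0, "C": 1e12}
        bare = g.InteractionModel(drugs=m.drugs)
        assert modulated_effect(m, "A", conc) == pytest.approx(
            perturbed_effect(bare, "A", conc), rel=1e-9
        )

    def test_nested_modulation_factor(self):
        # INT_AB = 1 scaled by (1 + 1 * C_C/(5 + C_C)) at C_C = 5 gives 1.5;
        # at saturating perpetrator dose the EC50 factor is 1 + 1.5 = 2.5
        m = self._three_drug_model(1.0)
        conc = {"A": 2.0 * 2.5 * 2.0, "B": 1e12, "C": 5.0}
        # victim A with EC50 2.0*2.5 at concentration 2x that: Hill=1.5
        expected = g.effect(g.SingleDrugPD("A", emax=1.0, ec50=5.0, hill=1.5), 10.0)
        assert modulated_effect(m, "A", conc) == pytest.approx(expected, rel=1e-9)

    def test_modulation_referencing_missing_term_rejected(self):
        a = g.SingleDrugPD("A", ec50=2.0)
        b = g.SingleDrugPD("B", ec50=1.0)
        c = g.SingleDrugPD("C", ec50=1.0)
        mod = g.GPDITerm("C", "A", int_value=1.0, ec50_int=5.0,
                         target_param="INT", modulated_pair=("B", "A"))
        with pytest.raises(ValueError):
            g.InteractionModel(drugs=(a, b, c), terms=(mod,))


class TestModelValidation:
    def test_loewe_rejects_emax_target_terms(self, drug_a, drug_b):
        with pytest.raises(ValueError):
            g.InteractionModel(
                drugs=(drug_a, drug_b),
                terms=(term(int_value=1.0, target_param="Emax"),),
                criterion="loewe",
            )

    def test_duplicate_terms_rejected(self, drug_a, drug_b):
        with pytest.raises(ValueError):
            g.InteractionModel(
                drugs=(drug_a, drug_b),
                terms=(term(int_value=1.0), term(int_value=2.0)),
            )

    def test_unknown_perpetrator_rejected(self, drug_a, drug_b):
        with pytest.raises(KeyError):
            g.InteractionModel(drugs=(drug_a, drug_b), terms=(term(perp="Z"),))


class TestSlopeModelShift:
    def test_zero_interaction_keeps_slope_model(self):
        d = g.SingleDrugPD("d", form="slope", slope=0.1)
        res = slope_model_shift(d, term(int_value=0.0), conc=5.0, perp_conc=3.0)
        assert res.effect == pytest.approx(0.5)

    def test_numerator_placement_multiplies(self):
        d = g.SingleDrugPD("d", form="slope", slope=0.1)
        res = slope_model_shift(d, term(int_value=1.0, ec50_int=1e-9), conc=5.0,
                                perp_conc=1.0, placement="numerator")
        assert res.effect == pytest.approx(1.0, rel=1e-6)
        assert "Emax" in res.interpretation

    def test_denominator_placement_divides(self):
        d = g.SingleDrugPD("d", form="slope", slope=0.1)
        res = slope_model_shift(d, term(int_value=1.0, ec50_int=1e-9), conc=5.0,
                                perp_conc=1.0, placement="denominator")
        assert res.effect == pytest.approx(0.25, rel=1e-6)
        assert "EC50" in res.interpretation

    def test_sigmoid_form_rejected(self, drug_a):
        with pytest.raises(TypeError):
            slope_model_shift(drug_a, term(), conc=1.0, perp_conc=1.0)
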