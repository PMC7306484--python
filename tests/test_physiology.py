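"""System-parameter maturation functions and the nine demographic anchors."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedrenal import physiology as phys

# label, height cm, weight kg, hematocrit %, BSA m^2
ANCHOR_DEMOGRAPHICS = [
    ("1 day", 49.75, 3.55, 56, 0.22),
    ("1 month", 54.25, 4.3, 44, 0.25),
    ("3 months", 60, 5.75, 35.5, 0.31),
    ("6 months", 66, 7.55, 36, 0.37),
    ("1 year", 74.75, 9.9, 36, 0.46),
    ("2 years", 86, 12.35, 36.5, 0.54),
    ("5 years", 108.25, 18.25, 37, 0.73),
    ("15 years", 166, 54.25, 42, 1.59),
    ("Adult", 169.5, 66.5, 44, 1.76),
]


@pytest.mark.parametrize("label,height,weight,hct,bsa", ANCHOR_DEMOGRAPHICS)
def test_anchor_demographics(label, height, weight, hct, bsa):
    ind = phys.individual(label)
    assert ind.height == pytest.approx(height)
    assert ind.weight == pytest.approx(weight)
    assert ind.hematocrit_fraction == pytest.approx(hct / 100)
    assert ind.bsa == pytest.approx(bsa)


def test_anchor_age_unit_consistency(individuals):
    for ind in individuals:
        assert ind.age_years == pytest.approx(ind.age_days / phys.DAYS_PER_YEAR)
        assert ind.pna_weeks == pytest.approx(ind.age_years * phys.WEEKS_PER_YEAR)
        assert ind.pma_weeks == pytest.approx(ind.pna_weeks + 40.0)


class TestGFR:
    def test_adult_reference_weight_asymptote(self):
        # at 70 kg and fully matured PMA both factors approach one
        assert phys.gfr_maturation(70, 1e9) == pytest.approx(112.0, rel=1e-6)

    def test_half_maximum_at_55_weeks(self):
        assert phys.gfr_maturation(70, 55.4) == pytest.approx(56.0)

    def test_adult_value(self):
        # direct evaluation of the formula at 66.5 kg / 1865 weeks
        assert phys.gfr_maturation(66.5, 1865) == pytest.approx(108.43760826805523)

    @pytest.mark.parametrize("weight,pma", [(0, 40), (-1, 40), (70, 0)])
    def test_domain_errors(self, weight, pma):
        with pytest.raises(ValueError):
            phys.gfr_maturation(weight, pma)


class TestProteinConcentration:
    def test_hsa_at_birth(self):
        assert phys.protein_concentration(1, "HSA") == pytest.approx(33.746)

    def test_agp_asymptote(self):
        assert phys.protein_concentration(1e12, "AGP") == pytest.approx(
            0.887, rel=1e-3
        )

    def test_hsa_adult(self):
        assert phys.protein_concentration(12775, "HSA") == pytest.approx(
            44.41813549999166
        )

    def test_agp_at_birth(self):
        assert phys.protein_concentration(1, "AGP") == pytest.approx(
            0.2692821136794099
        )

    def test_age_below_one_day_rejected(self):
        with pytest.raises(ValueError):
            phys.protein_concentration(0.5, "HSA")

    def test_unknown_protein_rejected(self):
        with pytest.raises(ValueError):
            phys.protein_concentration(100, "ALB")


class TestFuPediatric:
    def test_fully_unbound_drug_stays_unbound(self):
        for conc in (10.0, 44.4, 80.0):
            assert phys.fu_pediatric(1.0, conc, 44.4) == 1.0

    def test_identity_at_equal_concentrations(self):
        assert phys.fu_pediatric(0.5, 40.0, 40.0) == pytest.approx(0.5)

    def test_hand_evaluated_example(self):
        # fu_adult = 0.05, pediatric concentration at 75% of adult
        assert phys.fu_pediatric(0.05, 0.75 * 44.0, 44.0) == pytest.approx(
            1 / (1 + 0.95 * 0.75 / 0.05)
        )

    def test_zero_fu_rejected(self):
        with pytest.raises(ValueError):
            phys.fu_pediatric(0.0, 40.0, 44.0)

    @given(
        fu_lo=st.floats(0.01, 0.98),
        delta=st.floats(0.01, 0.5),
        conc=st.floats(20.0, 60.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_in_fu_adult(self, fu_lo, delta, conc):
        lo = phys.fu_pediatric(fu_lo, conc, 44.4)
        hi = phys.fu_pediatric(min(fu_lo + delta, 1.0), conc, 44.4)
        assert hi > lo


class TestRenalBloodFlow:
    def test_renal_fraction_newborn(self):
        assert phys.renal_fraction(0.0) == pytest.approx(0.0453)

    def test_renal_fraction_asymptote(self):
        # males saturate at 4.53 + 14.63 = 19.16 percent
        males = 4.53 + 14.63 * 1e9 / (0.1888 + 1e9)
        assert males == pytest.approx(19.16, rel=1e-6)
        assert phys.renal_fraction(1e9) == pytest.approx(
            (19.16 + 17.53) / 2 / 100, rel=1e-4
        )

    def test_adult_flow_physiological(self, adult):
        qr = phys.renal_blood_flow(adult)
        assert qr == pytest.approx(852.8811308667431)
        assert 600 < qr < 1500


class TestHematocrit:
    def test_newborn_limit(self):
        assert phys.hematocrit_maturation(0.0) == pytest.approx(0.53)
        assert phys.hematocrit_maturation(1e-9) == pytest.approx(0.53, abs=1e-3)

    def test_adult_near_tabulated(self):
        assert phys.hematocrit_maturation(35.0) == pytest.approx(0.44, abs=0.04)

    def test_age_one_year(self):
        assert phys.hematocrit_maturation(1.0) == pytest.approx(0.35774665288512)


class TestKidneyWeight:
    def test_one_kilogram(self):
        assert phys.kidney_weight(1.0) == pytest.approx(9.1035)

    def test_adult(self):
        assert phys.kidney_weight(66.5) == pytest.approx(271.5866238057869)

    @given(st.floats(0.5, 60.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_concave_in_weight(self, w):
        assert phys.kidney_weight(2 * w) < 2 * phys.kidney_weight(w)


class TestSystemParameters:
    def test_gfr_below_renal_flow_everywhere(self, individuals):
        for ind in individuals:
            sys = phys.system_parameters(ind)
            assert sys.gfr < sys.qr

    def test_cell_density_age_invariant(self, individuals):
        for ind in individuals:
            assert phys.system_parameters(ind).ptcpgk == 60.0

    def test_all_outputs_positive_finite(self, individuals):
        for ind in individuals:
            sys = phys.system_parameters(ind)
            for name in ("gfr", "qr", "co", "renal_fraction",
                         "hematocrit_fraction", "kidney_weight",
                         "hsa_conc", "agp_conc"):
                value = getattr(sys, name)
                assert value > 0 and math.isfinite(value)

    def test_growth_monotone_over_anchors(self, individuals):
        for field in ("gfr", "kidney_weight"):
            values = [getattr(phys.system_parameters(i), field)
                      for i in individuals]
            assert values == sorted(values)

    def test_renal_flow_monotone_over_pediatric_anchors(self, individuals):
        # Q_R rises through childhood; the cardiac index peaks in
        # adolescence, so the 15-year-old exceeds the adult and the adult
        # transition is excluded here
        values = [phys.system_parameters(i).qr for i in individuals
                  if i.label != "Adult"]
        assert values == sorted(values)

    def test_neonatal_filtration_far_below_adult(self, individuals):
        gfr = {i.label: phys.system_parameters(i).gfr for i in individuals}
        assert gfr["1 day"] < 0.1 * gfr["Adult"]

    def test_hematocrit_in_plausible_band(self, individuals):
        for ind in individuals:
            assert 0.3 < ind.hematocrit_fraction < 0.6
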