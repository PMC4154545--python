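"""Capacity conversions: staffing ratios, surgeon throughput, wards, RT staff/equipment."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncocap import (
    CapacityNorms,
    DomainError,
    Geography,
    IncidenceRecord,
    IncidenceTable,
    apply_city_minimum,
    compute_requirements,
    ratio_staff_need,
    rt_equipment_need,
    rt_staff_need,
    surgeon_need,
    ward_staffing,
)
from oncocap.types import RequirementSummary


class TestRatioStaffNeed:
    @pytest.mark.parametrize(
        "patients,rate,expected",
        [
            (160_296, 5, 802),   # radiation/clinical oncologists for the state
            (160_296, 2, 321),   # pathologists (and palliative care)
            (1000, 5, 5),        # exact block
            (12_026, 2, 25),     # ceil(24.05)
            (28_934, 2, 58),
            (0, 5, 0),
        ],
    )
    def test_examples(self, patients, rate, expected):
        assert ratio_staff_need(patients, rate) == expected

    def test_block_filling_oracle(self):
        """Ceiling formula equals filling discrete 1000-patient blocks:
        one professional covers 1000/rate patients."""
        for rate in (1, 2, 4, 5, 12):
            capacity_per_person = Fraction(1000, rate)
            for patients in range(0, 5001, 7):
                count, covered = 0, Fraction(0)
                while covered < patients:
                    count += 1
                    covered += capacity_per_person
                assert ratio_staff_need(patients, rate) == count

    @settings(max_examples=60, derandomize=True)
    @given(a=st.integers(0, 10**6), b=st.integers(0, 10**6), rate=st.integers(1, 20))
    def test_monotone_integer_subadditive(self, a, b, rate):
        na, nb = ratio_staff_need(a, rate), ratio_staff_need(b, rate)
        assert ratio_staff_need(a + b, rate) <= na + nb
        assert ratio_staff_need(max(a, b), rate) >= min(na, nb)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(DomainError):
            ratio_staff_need(10, 0)


class TestSurgeonNeed:
    @pytest.mark.parametrize(
        "patients,expected", [(480, 1), (960, 2), (74_860, 156), (0, 0), (1, 1)]
    )
    def test_examples(self, norms, patients, expected):
        # throughput: 2 surgeries/day x 5 days x 48 weeks = 480/year
        assert surgeon_need(patients, norms) == expected

    def test_negative_rejected(self, norms):
        with pytest.raises(DomainError):
            surgeon_need(-1, norms)


class TestWardStaffing:
    def test_state_bed_requirement(self, norms):
        staff = ward_staffing(2_892, norms)
        assert staff == {
            "wards": 121,
            "oncology_nurses": 1_815,
            "oncopharmacists": 484,
            "pharmacy_technicians": 726,
        }

    @pytest.mark.parametrize("beds,wards,nurses", [(24, 1, 15), (0, 0, 0), (25, 2, 30)])
    def test_ward_definition(self, norms, beds, wards, nurses):
        staff = ward_staffing(beds, norms)
        assert (staff["wards"], staff["oncology_nurses"]) == (wards, nurses)

    @settings(max_examples=60, derandomize=True)
    @given(beds=st.integers(0, 100_000))
    def test_staff_are_exact_ward_multiples(self, norms, beds):
        staff = ward_staffing(beds, norms)
        w = staff["wards"]
        assert staff["oncology_nurses"] == norms.nurses_per_ward * w
        assert staff["oncopharmacists"] == norms.oncopharmacists_per_ward * w
        assert staff["pharmacy_technicians"] == norms.pharmacy_techs_per_ward * w
        assert w * norms.ward_size_beds >= beds


class TestRtStaffAndEquipment:
    def test_state_rt_staff(self, norms):
        assert rt_staff_need(94_808, norms) == {
            "rt_technicians": 1_138,
            "medical_physicists": 380,
            "linac_engineers": 95,
            "rt_nurses": 380,
        }

    def test_stated_ratios_per_1000(self, norms):
        assert rt_staff_need(1000, norms) == {
            "rt_technicians": 12, "medical_physicists": 4,
            "linac_engineers": 1, "rt_nurses": 4,
        }
        assert all(v == 0 for v in rt_staff_need(0, norms).values())

    def test_state_equipment_two_unit_policy(self, norms):
        assert rt_equipment_need(94_808, nonstop_allowed=False, norms=norms) == {
            "teletherapy": 190, "brachytherapy": 95, "ct_simulator": 95,
            "tps": 95, "dosimetry_qa": 95,
        }

    @pytest.mark.parametrize(
        "patients,nonstop,tele,others",
        [(1000, True, 1, 1), (500, False, 2, 1), (0, False, 0, 0)],
    )
    def test_teletherapy_policy(self, norms, patients, nonstop, tele, others):
        eq = rt_equipment_need(patients, nonstop_allowed=nonstop, norms=norms)
        assert eq["teletherapy"] == tele
        assert eq["brachytherapy"] == others

    @settings(max_examples=60, derandomize=True)
    @given(patients=st.integers(0, 10**6))
    def test_doubling_relation(self, norms, patients):
        single = rt_equipment_need(patients, nonstop_allowed=True, norms=norms)
        double = rt_equipment_need(patients, nonstop_allowed=False, norms=norms)
        assert double["teletherapy"] == 2 * single["teletherapy"]
        assert double["brachytherapy"] == single["brachytherapy"]


class TestCityMinimum:
    def summary(self, level="city", **staff):
        return RequirementSummary(geography="C", level=level, staff=staff)

    @pytest.mark.parametrize("value,expected", [(1, 2), (5, 5), (0, 2), (2, 2)])
    def test_floor(self, norms, value, expected):
        out = apply_city_minimum(self.summary(pathologists=value), norms)
        assert out.staff["pathologists"] == expected
        assert ("pathologists" in out.floored) == (value < 2)

    def test_state_level_refused(self, norms):
        with pytest.raises(DomainError):
            apply_city_minimum(self.summary(level="state", pathologists=1), norms)


class TestComputeRequirements:
    def test_state_chain_with_published_overrides(
        self, up_incidence, fractions, norms, up_overrides
    ):
        from oncocap import compute_demand

        demand = compute_demand(up_incidence, fractions)
        req = compute_requirements(
            up_incidence, demand, norms, overrides=up_overrides
        )
        assert req.staff["radiation_clinical_oncologists"] == 802
        assert req.staff["pathologists"] == 321
        assert req.staff["palliative_care_specialists"] == 321
        assert req.staff["gynecologic_oncologists"] == 58
        assert req.staff["hematologist_oncologists"] == 25
        assert req.wards == 121
        assert req.staff["oncology_nurses"] == 1_815
        assert req.equipment["teletherapy"] == 190

    def test_override_replaces_computed_totals_only_downstream(
        self, up_incidence, fractions, norms, up_overrides
    ):
        from oncocap import compute_demand

        demand = compute_demand(up_incidence, fractions)
        req = compute_requirements(up_incidence, demand, norms, overrides=up_overrides)
        # computed demand is untouched; the override drives capacity only
        assert demand.totals.surgery == 68_212
        assert req.staff["surgical_oncologists"] == 156  # ceil(74860/480)

    def test_norms_are_overridable(self, up_incidence, fractions):
        from oncocap import compute_demand

        custom = CapacityNorms(rco_per_1000_cases=10)
        demand = compute_demand(up_incidence, fractions)
        req = compute_requirements(up_incidence, demand, custom)
        assert req.staff["radiation_clinical_oncologists"] == 1_603
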