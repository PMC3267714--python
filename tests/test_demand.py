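import math

import pytest
from hypothesis import given, strategies as st

from uhccost.demand import (StaffingNorms, allocate_specialty_visits,
                            beds_required, derive_admission_fractions,
                            estimate_demand, monthly_patient_load,
                            split_opd_ipd, staffing_plan)
from uhccost.params import ValidationError


class TestMonthlyLoad:
    @pytest.mark.parametrize("pop,rate,adj,expected", [
        (100_000, 0.1, 1.2, 12_000),
        (80_000, 0.08, 1.125, 7_200),
        (0, 0.1, 1.2, 0),
    ])
    def test_examples(self, pop, rate, adj, expected):
        assert monthly_patient_load(pop, rate, adj) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            monthly_patient_load(-1, 0.1, 1.2)

    @given(pop=st.floats(0, 1e7), rate=st.floats(0, 1), adj=st.floats(0, 3),
           k=st.floats(0.1, 10))
    def test_multiplicative_linearity(self, pop, rate, adj, k):
        base = monthly_patient_load(pop, rate, adj)
        assert monthly_patient_load(k * pop, rate, adj) == pytest.approx(k * base)
        assert monthly_patient_load(pop, k * rate, adj) == pytest.approx(k * base)


class TestSplit:
    @pytest.mark.parametrize("load,frac,expected", [
        (12_000, 0.9, (10_800, 1_200)),
        (12_000, 1.0, (12_000, 0)),
        (7_200, 0.9, (6_480, 720)),
    ])
    def test_examples(self, load, frac, expected):
        opd, ipd = split_opd_ipd(load, frac)
        assert (opd, ipd) == pytest.approx(expected)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValidationError):
            split_opd_ipd(100, 1.5)


class TestAllocation:
    def test_rounded_table_shares_land_near_printed(self):
        # coarse published shares: within +/-2 of the printed cells
        alloc = allocate_specialty_visits(10_800, {"general_medicine": 0.222,
                                                   "ent": 0.068, "rest": 0.710})
        assert abs(alloc["general_medicine"] - 2400) <= 2
        assert abs(alloc["ent"] - 735) <= 2

    def test_zero_total(self):
        assert allocate_specialty_visits(0, {"a": 0.5, "b": 0.5}) == {"a": 0, "b": 0}

    def test_negative_share_rejected(self):
        with pytest.raises(ValidationError):
            allocate_specialty_visits(100, {"a": -0.1, "b": 1.1})

    @given(total=st.integers(0, 100_000),
           weights=st.lists(st.floats(0.01, 1), min_size=1, max_size=12))
    def test_largest_remainder_preserves_total(self, total, weights):
        shares = {f"s{i}": w / sum(weights) for i, w in enumerate(weights)}
        alloc = allocate_specialty_visits(total, shares)
        assert sum(alloc.values()) == total
        assert all(v >= 0 for v in alloc.values())


class TestAdmissionFractions:
    def test_brute_force_oracle(self, profiles):
        # independent recomputation straight from the table row values
        fractions = derive_admission_fractions(profiles)
        assert fractions["general_medicine"] == pytest.approx((343 / 6.9) / 2400)
        assert fractions["general_medicine"] == pytest.approx(0.0207, abs=5e-4)
        assert fractions["psychiatry"] == pytest.approx((17 / 16.2) / 168)
        assert fractions["psychiatry"] == pytest.approx(0.00625, abs=5e-5)

    def test_zero_bed_days_gives_zero(self, profiles):
        from uhccost.params import SpecialtyProfile
        frac = derive_admission_fractions(
            [SpecialtyProfile("x", 100, 0, None)])
        assert frac["x"] == 0.0


class TestBeds:
    @pytest.mark.parametrize("bed_days,days,occ,expected", [
        (1984, 30, 1.0, 66),
        (0, 30, 1.0, 0),
        (1984, 30, 0.8, 83),  # 1984/24 = 82.7, half-up
    ])
    def test_examples(self, bed_days, days, occ, expected):
        assert beds_required(bed_days, days, occ) == expected

    def test_occupancy_bounds(self):
        with pytest.raises(ValidationError):
            beds_required(100, 30, 0.0)
        with pytest.raises(ValidationError):
            beds_required(100, 30, 1.2)

    @given(bd=st.floats(0, 1e5), extra=st.floats(0, 1e4),
           occ=st.floats(0.1, 1.0))
    def test_monotonicity(self, bd, extra, occ):
        assert beds_required(bd + extra, 30, occ) >= beds_required(bd, 30, occ)
        assert beds_required(bd, 30, occ) >= beds_required(bd, 30, 1.0)


class TestDemandChain:
    def test_regenerates_reference_table(self, profiles, reference_table):
        d = estimate_demand(100_000, 0.1, 1.2, 0.9, profiles)
        assert d.monthly_load == 12_000
        assert d.opd_visits_total == 10_800
        for name, (visits, bed_days, *_rest) in reference_table.items():
            assert abs(d.opd_visits_by_specialty[name] - visits) <= 2
            assert abs(d.bed_days_by_specialty[name] - bed_days) <= 1
        assert d.beds_required == 66

    def test_bed_days_consistent_with_admissions(self, profiles):
        d = estimate_demand(100_000, 0.1, 1.2, 0.9, profiles)
        for p in profiles:
            if p.alos_days is not None:
                assert d.bed_days_by_specialty[p.name] == pytest.approx(
                    d.ipd_admissions_by_specialty[p.name] * p.alos_days)

    def test_zero_population(self, profiles):
        d = estimate_demand(0, 0.1, 1.2, 0.9, profiles)
        assert d.beds_required == 0
        assert d.total_bed_days == 0


class TestStaffing:
    def test_zero_demand_plan(self, profiles):
        d = estimate_demand(0, 0.1, 1.2, 0.9, profiles)
        plan = staffing_plan(d, StaffingNorms(), population=0)
        assert plan.total_specialists == 0
        assert plan.nurses == plan.medical_officers == plan.technicians == 0
        assert plan.anms == 0
        assert plan.admin == StaffingNorms().admin_team_size

    def test_monotone_in_load(self, profiles):
        norms = StaffingNorms()
        d1 = estimate_demand(100_000, 0.1, 1.2, 0.9, profiles)
        d2 = estimate_demand(200_000, 0.1, 1.2, 0.9, profiles)
        p1 = staffing_plan(d1, norms, 100_000)
        p2 = staffing_plan(d2, norms, 200_000)
        assert p2.total_specialists >= p1.total_specialists
        assert p2.nurses >= p1.nurses and p2.medical_officers >= p1.medical_officers

    def test_calibrated_norm_reproduces_medicine_specialists(self, profiles):
        # 2400 recorded visits/month over 24 clinic days at 25 consults/day -> 4
        from uhccost.demand import DemandEstimate
        d = DemandEstimate(
            monthly_load=12_000, opd_visits_total=10_799,
            opd_visits_by_specialty={p.name: int(p.monthly_opd_visits)
                                     for p in profiles},
            ipd_admissions_by_specialty={}, bed_days_by_specialty={},
            beds_required=66)
        plan = staffing_plan(d, StaffingNorms(), 100_000)
        assert plan.specialists_by_specialty["general_medicine"] == 4
        assert plan.anms == 20  # 1 per 5000 population

    def test_invalid_norm_rejected(self):
        with pytest.raises(ValidationError):
            StaffingNorms(beds_per_nurse=0).validate()
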