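import math

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import soilpem as sp
from soilpem.enzymes import (PlateLayout, enzyme_ratios, enzyme_vector,
                             fluorescence_to_activity, vector_summary)

activities = st.floats(min_value=1.0, max_value=5000.0, allow_nan=False)


def make_row(bg, cbh, nag, lap, alp):
    return pd.Series({"BG": bg, "CBH": cbh, "NAG": nag, "LAP": lap, "ALP": alp})


class TestFluorescenceToActivity:
    def _plate(self, assay, quench=0.8, emission=100.0, **kw):
        defaults = dict(blank=50.0, negative_control=10.0,
                        incubation_time=3.0, soil_mass=0.5,
                        homogenate_volume=50.0, aliquot_volume=200.0,
                        standard_amount=0.5)
        defaults.update(kw)
        reference = emission * defaults["standard_amount"]
        return PlateLayout(assay=assay,
                           quench_standard=defaults["blank"] + quench * reference,
                           reference_standard=reference, **defaults)

    def test_no_signal_gives_zero(self):
        plate = self._plate(assay=50.0 + 10.0 * 0.8)
        assert fluorescence_to_activity(plate) == 0.0

    def test_forward_simulated_activity_recovered(self):
        # forward-simulate the fluorescence a known activity A would produce
        A = 123.456  # nmol h-1 g-1
        quench, emission = 0.8, 100.0
        time_h, mass, vol, aliquot = 3.0, 0.5, 50.0, 200.0
        soil_per_well = mass * (aliquot / 1000.0) / vol
        nmol = A * time_h * soil_per_well
        assay = 50.0 + nmol * emission * quench + 10.0 * quench
        plate = self._plate(assay=assay, quench=quench, emission=emission)
        assert fluorescence_to_activity(plate) == pytest.approx(A, rel=1e-9)

    def test_doubling_soil_mass_halves_activity(self):
        plate = self._plate(assay=500.0)
        a1 = fluorescence_to_activity(plate)
        plate2 = self._plate(assay=500.0, soil_mass=1.0)
        assert fluorescence_to_activity(plate2) == pytest.approx(a1 / 2.0)

    def test_degenerate_standards_fatal(self):
        plate = self._plate(assay=500.0)
        plate.reference_standard = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            fluorescence_to_activity(plate)


class TestRatios:
    def test_exact_log_values(self):
        e = math.e
        row = make_row(e ** 2 / 2, e ** 2 / 2, e / 2, e / 2, e)
        r = enzyme_ratios(row)
        assert (r.ec_n, r.ec_p, r.en_p) == pytest.approx((2.0, 2.0, 1.0))

    def test_worked_example(self):
        r = enzyme_ratios(make_row(60, 40, 20, 30, 80))
        assert r.ec_n == pytest.approx(1.1772, abs=1e-4)
        assert r.ec_p == pytest.approx(1.0509, abs=1e-4)
        assert r.en_p == pytest.approx(0.8927, abs=1e-4)

    def test_boundary_sum_flagged(self):
        r = enzyme_ratios(make_row(10, 10, 0.5, 0.5, 10))
        assert r.flagged and math.isnan(r.ec_n)


class TestVector:
    def test_symmetric_point_is_balanced(self):
        # x = y = 0.5 when ALP equals NAG+LAP equals BG+CBH
        v = enzyme_vector(make_row(50, 50, 40, 60, 100))
        assert v.x == pytest.approx(0.5) and v.y == pytest.approx(0.5)
        assert v.length == pytest.approx(0.7071, abs=1e-4)
        assert v.angle == pytest.approx(45.0)
        assert v.limitation == "balanced"

    def test_worked_example_p_limited(self):
        v = enzyme_vector(make_row(60, 40, 20, 30, 80))
        assert v.x == pytest.approx(0.5556, abs=1e-4)
        assert v.y == pytest.approx(0.6667, abs=1e-4)
        assert v.length == pytest.approx(0.8678, abs=1e-4)
        assert v.angle == pytest.approx(50.19, abs=0.01)
        assert v.limitation == "P_limited"

    def test_arctangent_evaluation_n_limited(self):
        angle = math.degrees(math.atan2(0.35, 0.8))
        assert angle == pytest.approx(23.63, abs=0.01)
        # realize x=0.8, y=0.35 with activities: C=80, ALP=20, N=148.57
        v = enzyme_vector(make_row(40, 40, 70, 78.5714285714, 20))
        assert v.angle == pytest.approx(23.63, abs=0.01)
        assert v.limitation == "N_limited"

    @given(c=st.floats(min_value=1e-3, max_value=1e3),
           bg=activities, cbh=activities, nag=activities, lap=activities,
           alp=activities)
    @settings(max_examples=50, deadline=None)
    def test_angle_scale_invariant(self, c, bg, cbh, nag, lap, alp):
        v1 = enzyme_vector(make_row(bg, cbh, nag, lap, alp))
        v2 = enzyme_vector(make_row(c * bg, c * cbh, c * nag, c * lap, c * alp))
        assert v2.x == pytest.approx(v1.x, rel=1e-9)
        assert v2.y == pytest.approx(v1.y, rel=1e-9)
        assert v2.angle == pytest.approx(v1.angle, rel=1e-9)

    @given(x=st.floats(min_value=0.01, max_value=0.99),
           y=st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=50, deadline=None)
    def test_complementary_angles_sum_to_ninety(self, x, y):
        a_xy = math.degrees(math.atan2(y, x))
        a_yx = math.degrees(math.atan2(x, y))
        assert a_xy + a_yx == pytest.approx(90.0)

    def test_length_increases_in_c_enzymes(self):
        lengths = [enzyme_vector(make_row(bg, 0, 50, 50, 80)).length
                   for bg in (10, 50, 100, 500)]
        assert lengths == sorted(lengths)

    def test_limitation_flips_at_45_degrees(self):
        just_p = enzyme_vector(make_row(50, 50, 40, 59.9, 100))
        just_n = enzyme_vector(make_row(50, 50, 40, 60.1, 100))
        assert just_p.limitation == "P_limited"
        assert just_n.limitation == "N_limited"


class TestVectorSummary:
    def test_identical_samples_zero_se_single_letter(self):
        meta = sp.SampleMetadata.from_records(
            [(f"{t}_{r}", t, r) for t in ("CK", "OPT") for r in (1, 2, 3)])
        data = pd.DataFrame([make_row(60, 40, 20, 30, 80)] * 6,
                            index=meta.sample_ids)
        out = vector_summary(sp.EnzymeActivityTable(data), meta)
        tab = out["vector_angle"]
        assert (tab["se"] == 0).all()
        assert set(tab["letters"]) == {"a"}

    def test_separated_angle_means_get_distinct_letters(self, rng):
        meta = sp.SampleMetadata.from_records(
            [(f"{t}_{r}", t, r) for t in ("CK", "OPTP") for r in range(1, 5)])
        rows = []
        for sid in meta.sample_ids:
            target = 24.5 if sid.startswith("CK") else 22.0
            angle = rng.normal(target, 0.3)
            # build activities with the desired angle: fix x=0.5, y=x*tan(angle)
            x, y = 0.5, 0.5 * math.tan(math.radians(angle))
            c = 100.0
            alp = c / x - c
            n = c / y - c
            rows.append(make_row(60, 40, n / 2, n / 2, alp))
        data = pd.DataFrame(rows, index=meta.sample_ids)
        out = vector_summary(sp.EnzymeActivityTable(data), meta)
        letters = out["vector_angle"]["letters"]
        assert letters["CK"] != letters["OPTP"]

    def test_negative_coupling_gives_negative_slope(self, rng):
        meta = sp.SampleMetadata.from_records(
            [(f"CK_{r}", "CK", r) for r in range(1, 6)]
            + [(f"OPT_{r}", "OPT", r) for r in range(1, 6)])
        rows = []
        for i, sid in enumerate(meta.sample_ids):
            # angle decreases as length increases across samples
            x = 0.4 + 0.05 * i
            angle = 30.0 - 1.2 * i + rng.normal(0, 0.1)
            y = x * math.tan(math.radians(angle))
            c = 100.0
            rows.append(make_row(60, 40, (c / y - c) / 2, (c / y - c) / 2,
                                 c / x - c))
        data = pd.DataFrame(rows, index=meta.sample_ids)
        out = vector_summary(sp.EnzymeActivityTable(data), meta)
        assert out["angle_on_length"]["slope"] < 0
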