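"""Factor coding and composite relative risks."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bcrisk as b
from bcrisk.profiles import bundled_scheme_path, read_scheme_csv, read_profiles_csv

from conftest import worked_example_measurements


def test_default_scheme_has_six_factors_with_reference_rr_one(scheme):
    assert len(scheme.factors) == 6
    assert set(scheme.factor_names) == {
        "abortions",
        "age_first_live_birth",
        "benign_breast_disease",
        "bmi",
        "family_history",
        "life_satisfaction",
    }
    for spec in scheme.factors:
        assert spec.rr_per_code[0] == 1.0
        assert all(rr > 0 and math.isfinite(rr) for rr in spec.rr_per_code)


def test_bundled_scheme_csv_matches_default(scheme):
    from_csv = read_scheme_csv(str(bundled_scheme_path()))
    assert from_csv == scheme


@pytest.mark.parametrize(
    "raw, expected",
    [
        # BMI 27 -> overweight category
        (dict(weight_kg=27.0, height_m=1.0), {"bmi": 1}),
        # boundary: 24 enters overweight, 28 enters obese, 27.95 stays overweight
        (dict(weight_kg=24.0, height_m=1.0), {"bmi": 1}),
        (dict(weight_kg=27.95, height_m=1.0), {"bmi": 1}),
        (dict(weight_kg=28.0, height_m=1.0), {"bmi": 2}),
        (dict(weight_kg=20.0, height_m=1.0), {"bmi": 0}),
        (dict(n_abortions=0), {"abortions": 0}),
        (dict(n_abortions=2), {"abortions": 1}),
        (dict(n_abortions=3), {"abortions": 2}),
        (dict(age_first_live_birth=24.9), {"age_first_live_birth": 0}),
        (dict(age_first_live_birth=25), {"age_first_live_birth": 1}),
        (dict(age_first_live_birth=30), {"age_first_live_birth": 2}),
        # satisfaction total 13 is unsatisfied, 12 is not
        (dict(satisfaction_items=(3, 2, 2, 2, 2, 2)), {"life_satisfaction": 1}),
        (dict(satisfaction_items=(2, 2, 2, 2, 2, 2)), {"life_satisfaction": 0}),
    ],
)
def test_encoding_cut_points(scheme, raw, expected):
    base = dict(
        n_abortions=0,
        age_first_live_birth=22,
        benign_breast_disease=False,
        height_m=1.0,
        weight_kg=20.0,
        family_history=False,
        satisfaction_items=(1, 1, 1, 1, 1, 1),
    )
    base.update(raw)
    profile = b.encode_profile(b.RawMeasurements(**base), scheme)
    for name, code in expected.items():
        assert profile.codes[name] == code


def test_reference_inputs_code_all_zero_and_rr_one(scheme):
    raw = b.RawMeasurements(
        n_abortions=0,
        age_first_live_birth=22,
        benign_breast_disease=False,
        height_m=1.60,
        weight_kg=20 * 1.60**2,
        family_history=False,
        satisfaction_items=(1, 1, 1, 1, 1, 1),
    )
    profile = b.encode_profile(raw, scheme)
    assert all(code == 0 for code in profile.codes.values())
    assert b.composite_rr(profile, scheme) == 1.0


def test_worked_example_codes_and_composite_rr(scheme):
    profile = b.encode_profile(worked_example_measurements(), scheme)
    assert profile.codes == {
        "abortions": 1,
        "age_first_live_birth": 1,
        "benign_breast_disease": 0,
        "bmi": 1,
        "family_history": 1,
        "life_satisfaction": 0,
    }
    assert round(b.composite_rr(profile, scheme), 2) == 21.23


def test_composite_rr_hand_multiplied(scheme):
    # three or more abortions with benign breast disease, all else reference
    profile = b.RiskProfile(
        codes={
            "abortions": 2,
            "age_first_live_birth": 0,
            "benign_breast_disease": 1,
            "bmi": 0,
            "family_history": 0,
            "life_satisfaction": 0,
        }
    )
    assert round(b.composite_rr(profile, scheme), 2) == round(6.313 * 4.255, 2) == 26.86


def test_nulliparous_default_reference_and_configurable(scheme, caplog):
    raw = b.RawMeasurements(
        n_abortions=0,
        age_first_live_birth=None,
        benign_breast_disease=False,
        height_m=1.6,
        weight_kg=50,
        family_history=False,
        satisfaction_items=(1, 1, 1, 1, 1, 1),
    )
    with caplog.at_level("WARNING"):
        profile = b.encode_profile(raw, scheme)
    assert profile.codes["age_first_live_birth"] == 0
    assert any("nulliparous" in r.message for r in caplog.records)
    alt = b.encode_profile(raw, scheme, nulliparous_code=1)
    assert alt.codes["age_first_live_birth"] == 1


@pytest.mark.parametrize(
    "bad",
    [
        dict(n_abortions=-1),
        dict(height_m=0.0),
        dict(satisfaction_items=(1, 1, 1, 1, 1)),
        dict(satisfaction_items=(1, 1, 1, 1, 1, 6)),
    ],
)
def test_invalid_measurements_rejected(bad):
    base = dict(
        n_abortions=0,
        age_first_live_birth=22,
        benign_breast_disease=False,
        height_m=1.6,
        weight_kg=50,
        family_history=False,
        satisfaction_items=(1, 1, 1, 1, 1, 1),
    )
    base.update(bad)
    with pytest.raises(ValueError):
        b.RawMeasurements(**base)


def test_out_of_range_code_rejected(scheme):
    profile = b.RiskProfile(
        codes={n: 0 for n in scheme.factor_names} | {"family_history": 2}
    )
    with pytest.raises(ValueError, match="family_history"):
        b.composite_rr(profile, scheme)


@given(
    codes=st.tuples(
        st.integers(0, 2),
        st.integers(0, 2),
        st.integers(0, 1),
        st.integers(0, 2),
        st.integers(0, 1),
        st.integers(0, 1),
    ),
    factor=st.integers(0, 5),
)
@settings(deadline=None, derandomize=True)
def test_composite_rr_is_multiplicative_in_each_factor(codes, factor):
    """Changing one factor's code scales the product by the RR ratio."""
    scheme = b.default_scheme()
    names = scheme.factor_names
    profile = b.RiskProfile(codes=dict(zip(names, codes)))
    spec = scheme.factors[factor]
    old_code = codes[factor]
    new_code = (old_code + 1) % spec.n_levels
    changed = b.RiskProfile(codes={**profile.codes, spec.name: new_code})
    ratio = spec.rr_per_code[new_code] / spec.rr_per_code[old_code]
    assert b.composite_rr(changed, scheme) == pytest.approx(
        b.composite_rr(profile, scheme) * ratio, rel=1e-12
    )
    # all published non-reference RRs exceed 1, so the product never drops below 1
    assert b.composite_rr(profile, scheme) >= 1.0


def test_composite_rr_is_factor_order_invariant(scheme):
    reordered = b.RiskFactorScheme(factors=tuple(reversed(scheme.factors)))
    profile = b.RiskProfile(
        codes={
            "abortions": 1,
            "age_first_live_birth": 2,
            "benign_breast_disease": 1,
            "bmi": 1,
            "family_history": 0,
            "life_satisfaction": 1,
        }
    )
    assert b.composite_rr(profile, scheme) == pytest.approx(
        b.composite_rr(profile, reordered), rel=1e-12
    )


def test_profiles_csv_roundtrip_coded_and_raw(tmp_path, scheme):
    coded = tmp_path / "coded.csv"
    coded.write_text(
        "abortions,age_first_live_birth,benign_breast_disease,bmi,"
        "family_history,life_satisfaction\n1,1,0,1,1,0\n0,0,0,0,0,0\n"
    )
    profiles = read_profiles_csv(coded, scheme)
    assert round(b.composite_rr(profiles[0], scheme), 2) == 21.23
    assert b.composite_rr(profiles[1], scheme) == 1.0
    # re-encoding an already-coded profile is the identity
    assert profiles[0] == read_profiles_csv(coded, scheme, coded=True)[0]

    raw = tmp_path / "raw.csv"
    raw.write_text(
        "n_abortions,age_first_live_birth,benign_breast_disease,height_m,weight_kg,"
        "family_history,satisfaction_1,satisfaction_2,satisfaction_3,satisfaction_4,"
        "satisfaction_5,satisfaction_6\n"
        "1,27,0,1.6,69.12,1,1,1,1,1,1,2\n"
    )
    (profile,) = read_profiles_csv(raw, scheme)
    assert profile == profiles[0]
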