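import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matchboot.data_model import ValidationError, default_schema
from matchboot.endpoints import (
    aalen_johansen,
    cif_from_cohort,
    cif_tidy,
    curb65,
    curb65_scores,
    endpoint_panel,
    filter_complete_case,
    filter_micro_confirmed,
    filter_severe,
)
from matchboot.propensity_match import MatchResult
from matchboot.synthetic_cohort import SimulationConfig, generate_cohort

from conftest import make_cohort


def _paired(cohort):
    """Pair every treated patient with one control, in row order."""
    df = cohort.df
    t = df[df.arm == "BLM"]["id"].tolist()
    c = df[df.arm == "BL"]["id"].tolist()
    return MatchResult(pairs=list(zip(t, c)), caliper_width=1.0)


class TestEndpointPanel:
    def test_death_frequencies_and_difference(self):
        rows = []
        for i in range(4):
            rows.append({"id": f"t{i}", "arm": "BLM",
                         "outcome": "death" if i == 0 else "recovery"})
            rows.append({"id": f"c{i}", "arm": "BL", "outcome": "recovery"})
        cohort = make_cohort(rows)
        panel = endpoint_panel(cohort, _paired(cohort))
        assert panel.per_arm["BLM"]["death_pct"] == 25.0
        assert panel.per_arm["BL"]["death_pct"] == 0.0
        assert panel.differences["death_pct"] == 25.0

    def test_identical_outcomes_zero_differences(self):
        rows = []
        for i in range(3):
            rows.append({"id": f"t{i}", "arm": "BLM", "outcome": "recovery"})
            rows.append({"id": f"c{i}", "arm": "BL", "outcome": "recovery"})
        cohort = make_cohort(rows)
        panel = endpoint_panel(cohort, _paired(cohort))
        assert panel.differences["death_pct"] == 0.0
        assert panel.differences["abx_days"] == 0.0

    def test_abx_days_hand_arithmetic(self):
        rows = [
            {"id": "t0", "arm": "BLM", "abx_days": 7.0},
            {"id": "t1", "arm": "BLM", "abx_days": 9.0},
            {"id": "c0", "arm": "BL", "abx_days": 10.0},
            {"id": "c1", "arm": "BL", "abx_days": 10.0},
        ]
        cohort = make_cohort(rows)
        panel = endpoint_panel(cohort, _paired(cohort))
        assert panel.per_arm["BLM"]["abx_days"] == 8.0
        assert panel.per_arm["BL"]["abx_days"] == 10.0
        assert panel.differences["abx_days"] == -2.0

    def test_los_only_over_inpatients(self):
        rows = [
            {"id": "t0", "arm": "BLM", "los_days": 12.0},
            {"id": "t1", "arm": "BLM", "outpatient": 1},  # los cleared
            {"id": "c0", "arm": "BL", "los_days": 20.0},
            {"id": "c1", "arm": "BL", "outpatient": 1},
        ]
        cohort = make_cohort(rows)
        panel = endpoint_panel(cohort, _paired(cohort))
        assert panel.per_arm["BLM"]["los_days"] == 12.0
        assert panel.per_arm["BL"]["los_days"] == 20.0
        assert panel.differences["los_days"] == -8.0

    def test_no_inpatients_marks_unavailable(self):
        rows = [
            {"id": "t0", "arm": "BLM", "outpatient": 1},
            {"id": "c0", "arm": "BL", "outpatient": 1},
        ]
        cohort = make_cohort(rows)
        panel = endpoint_panel(cohort, _paired(cohort))
        assert panel.per_arm["BLM"]["los_days"] is None
        assert panel.differences["los_days"] is None

    def test_empty_match_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValidationError):
            endpoint_panel(cohort, MatchResult(pairs=[], caliper_width=0.0))

    def test_antisymmetric_under_arm_relabel(self):
        rows = [
            {"id": "t0", "arm": "BLM", "outcome": "death", "abx_days": 4.0},
            {"id": "c0", "arm": "BL", "outcome": "recovery", "abx_days": 9.0},
        ]
        cohort = make_cohort(rows)
        panel = endpoint_panel(cohort, _paired(cohort))
        flipped = make_cohort(
            [
                {"id": "t0", "arm": "BL", "outcome": "death", "abx_days": 4.0},
                {"id": "c0", "arm": "BLM", "outcome": "recovery", "abx_days": 9.0},
            ]
        )
        panel_f = endpoint_panel(
            flipped, MatchResult(pairs=[("c0", "t0")], caliper_width=1.0)
        )
        for key in ("death_pct", "abx_days"):
            assert panel.differences[key] == -panel_f.differences[key]


class TestCurb65:
    def test_all_absent_zero(self):
        assert curb65(False, 10.0, 18.0, 120.0, 40.0) == 0

    def test_all_present_five(self):
        assert curb65(True, 30.0, 32.0, 85.0, 80.0) == 5

    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(impaired_consciousness=False, bun=10, respiratory_rate=20, systolic_bp=120, age=65), 1),
            (dict(impaired_consciousness=False, bun=19.6, respiratory_rate=20, systolic_bp=120, age=40), 0),
            (dict(impaired_consciousness=False, bun=19.7, respiratory_rate=20, systolic_bp=120, age=40), 1),
            (dict(impaired_consciousness=False, bun=10, respiratory_rate=30, systolic_bp=120, age=40), 1),
            (dict(impaired_consciousness=False, bun=10, respiratory_rate=20, systolic_bp=90, age=40), 0),
            (dict(impaired_consciousness=False, bun=10, respiratory_rate=20, systolic_bp=89.9, age=40), 1),
        ],
    )
    def test_boundary_rules(self, kwargs, expected):
        assert curb65(**kwargs) == expected

    @given(
        conf=st.booleans(),
        bun=st.floats(0, 100),
        rr=st.floats(0, 60),
        sbp=st.floats(40, 250),
        age=st.floats(0, 110),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_component(self, conf, bun, rr, sbp, age):
        base = curb65(conf, bun, rr, sbp, age)
        assert curb65(True, bun, rr, sbp, age) >= base
        assert curb65(conf, bun + 10, rr, sbp, age) >= base
        assert curb65(conf, bun, rr + 10, sbp, age) >= base
        assert curb65(conf, bun, rr, sbp - 10, age) >= base
        assert curb65(conf, bun, rr, sbp, age + 10) >= base

    def test_vectorized_matches_scalar(self, small_cohort):
        cohort, _ = small_cohort
        scores = curb65_scores(cohort)
        for _, row in cohort.df.head(20).iterrows():
            expected = curb65(
                bool(row["impaired_consciousness"]), row["bun"],
                row["respiratory_rate"], row["systolic_bp"], row["age"],
            )
            assert scores[row["id"]] == expected


class TestFilters:
    def test_severe_all_zero_empty(self):
        cohort = make_cohort([{"age": 40.0}, {"age": 50.0, "id": "b"}])
        assert filter_severe(cohort).n == 0

    def test_severe_counts_match_definition(self, small_cohort):
        cohort, _ = small_cohort
        scores = curb65_scores(cohort)
        sub = filter_severe(cohort)
        assert sub.n == int((scores >= 3).sum())

    def test_severe_requires_complete_components(self):
        cohort = make_cohort([{"bun": np.nan}])
        with pytest.raises(ValidationError):
            filter_severe(cohort)

    def test_micro_all_false_empty(self):
        cohort = make_cohort([{}, {"id": "b"}])
        assert filter_micro_confirmed(cohort).n == 0

    def test_micro_cfu_boundary_inclusive(self):
        cohort = make_cohort([{"sputum_quality": 1, "sputum_cfu": 1e6}])
        assert filter_micro_confirmed(cohort).n == 1

    def test_micro_quality_gate(self):
        cohort = make_cohort([{"sputum_quality": 0, "sputum_cfu": 1e9}])
        assert filter_micro_confirmed(cohort).n == 0

    def test_micro_semiquant_route(self):
        cohort = make_cohort([{"sputum_quality": 1, "sputum_semiquant": 3.0}])
        assert filter_micro_confirmed(cohort).n == 1

    def test_micro_other_criteria(self):
        cohort = make_cohort(
            [{"blood_culture_positive": 1}, {"id": "b", "urinary_antigen_positive": 1}]
        )
        assert filter_micro_confirmed(cohort).n == 2

    def test_micro_missing_columns_listed(self):
        spec = [s for s in default_schema() if s.name != "sputum_cfu"]
        cohort = make_cohort([{}], spec=spec)
        with pytest.raises(ValidationError, match="sputum_cfu"):
            filter_micro_confirmed(cohort)

    def test_complete_case_identity_when_complete(self, small_cohort):
        cohort, _ = small_cohort
        assert filter_complete_case(cohort).n == cohort.n

    def test_complete_case_all_incomplete_empty(self):
        cohort = make_cohort([{"bun": np.nan}, {"id": "b", "albumin": np.nan}])
        assert filter_complete_case(cohort).n == 0

    def test_complete_case_counting(self):
        cohort = make_cohort([{}, {"id": "b", "bun": np.nan}, {"id": "c"}])
        assert filter_complete_case(cohort).n == 2

    def test_complete_case_partitions_input(self, masked_cohort):
        cohort, _ = masked_cohort
        cc = filter_complete_case(cohort)
        incomplete = cohort.missing_mask().any(axis=1)
        assert cc.n + int(incomplete.sum()) == cohort.n


class TestAalenJohansen:
    def test_two_patient_worked_example(self):
        curve = aalen_johansen([1.0, 2.0], ["death", "recovery"])
        assert curve.cif("death", 0.5) == 0.0
        assert curve.cif("death", 1.0) == 0.5
        assert curve.cif("death", 5.0) == 0.5
        assert curve.cif("recovery", 1.5) == 0.0
        assert curve.cif("recovery", 2.0) == 0.5

    def test_single_cause_equals_one_minus_km(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(11)
        times = rng.exponential(10.0, size=200)
        cens = rng.random(200) < 0.3
        causes = np.where(cens, "censored", "death")
        curve = aalen_johansen(times, causes)
        km = KaplanMeierFitter().fit(times, event_observed=~cens)
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            expected = 1.0 - float(km.survival_function_at_times(t).iloc[0])
            assert curve.cif("death", t) == pytest.approx(expected, abs=1e-12)

    def test_no_censoring_mass_conservation(self):
        rng = np.random.default_rng(12)
        times = rng.exponential(5.0, size=300)
        causes = np.where(rng.random(300) < 0.4, "death", "recovery")
        curve = aalen_johansen(times, causes)
        total = curve.grid["cif_death"] + curve.grid["cif_recovery"] + curve.grid["km_survival"]
        assert np.allclose(total, 1.0, atol=1e-12)
        # CIF at infinity = cause proportions
        assert curve.final("death") == pytest.approx((causes == "death").mean(), abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            aalen_johansen([-1.0], ["death"])

    def test_unknown_cause_rejected(self):
        with pytest.raises(ValidationError):
            aalen_johansen([1.0], ["vanished"])

    def test_curves_nondecreasing(self, small_cohort):
        cohort, _ = small_cohort
        curves = cif_from_cohort(cohort)
        for curve in curves.values():
            for c in curve.causes:
                assert (np.diff(curve.grid[f"cif_{c}"]) >= -1e-15).all()

    def test_tidy_export_shape(self, small_cohort):
        cohort, _ = small_cohort
        tidy = cif_tidy(cif_from_cohort(cohort))
        assert set(tidy.columns) == {"arm", "time", "cause", "estimate"}
        assert set(tidy["arm"]) == {"BLM", "BL"}
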