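"""Cohort data model: I/O, normalization, filters, motor phenotype."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdelay.cohort import (
    Cohort,
    DegenerateDataError,
    OutcomeSpec,
    RangeError,
    ReferentialError,
    SchemaError,
    StateError,
    UniquenessError,
    apply_inclusion_filters,
    classify_motor_phenotype,
    normalize_outcomes,
    read_cohort,
    write_cohort,
)


def _cohort(measurements, specs, ids=None, ages=None):
    ids = ids or sorted(set(measurements["individual_id"]))
    individuals = pd.DataFrame(
        {
            "age_at_diagnosis": ages or [60.0] * len(ids),
            "sex": ["male"] * len(ids),
        },
        index=pd.Index(ids, name="individual_id"),
    )
    return Cohort("test", individuals, measurements, specs)


class TestConstructionAndIO:
    def test_direct_construction(self, tiny_cohort):
        assert len(tiny_cohort.measurements) == 3
        assert tiny_cohort.individual_ids == ["p1"]
        assert tiny_cohort.ltjmm_outcomes() == ["updrs3"]

    def test_unknown_outcome_is_referential_error(self):
        m = pd.DataFrame(
            {
                "individual_id": ["p1"],
                "outcome": ["mystery"],
                "time_years": [0.0],
                "value": [1.0],
            }
        )
        with pytest.raises(ReferentialError):
            _cohort(m, {"updrs3": OutcomeSpec("updrs3", "continuous", 0, 132)})

    def test_unknown_individual_is_referential_error(self, tiny_cohort):
        m = tiny_cohort.measurements.copy()
        m.loc[0, "individual_id"] = "ghost"
        with pytest.raises(ReferentialError):
            Cohort("x", tiny_cohort.individuals, m, tiny_cohort.specs)

    def test_duplicate_rows_are_uniqueness_error(self, tiny_cohort):
        m = pd.concat([tiny_cohort.measurements, tiny_cohort.measurements.iloc[[0]]])
        with pytest.raises(UniquenessError):
            Cohort("x", tiny_cohort.individuals, m, tiny_cohort.specs)

    def test_ltjmm_flag_requires_continuous(self):
        with pytest.raises(SchemaError):
            OutcomeSpec("hy", "ordinal", 1, 5, in_ltjmm=True)

    def test_degenerate_range_rejected(self):
        with pytest.raises(SchemaError):
            OutcomeSpec("x", "continuous", 5, 5)

    def test_individual_record_invariants(self):
        from pdelay.cohort import IndividualRecord

        rec = IndividualRecord("p1", 63.0, "female")
        assert rec.progression_subtype is None
        with pytest.raises(SchemaError):
            IndividualRecord("p2", -1.0, "male")
        with pytest.raises(SchemaError):
            IndividualRecord("p3", 60.0, "other")

    def test_roundtrip_is_exact(self, tiny_cohort, tmp_path):
        paths = write_cohort(tiny_cohort, tmp_path)
        back = read_cohort(
            paths["visits"], paths["individuals"], paths["specs"], name="tiny"
        )
        pd.testing.assert_frame_equal(
            back.measurements, tiny_cohort.measurements, check_dtype=False
        )
        assert back.specs == tiny_cohort.specs
        assert list(back.individuals.index) == list(tiny_cohort.individuals.index)

    def test_missing_column_names_column(self, tiny_cohort, tmp_path):
        paths = write_cohort(tiny_cohort, tmp_path)
        df = pd.read_csv(paths["visits"]).drop(columns=["value"])
        df.to_csv(paths["visits"], index=False)
        with pytest.raises(SchemaError, match="value"):
            read_cohort(paths["visits"], paths["individuals"], paths["specs"])

    def test_missing_values_dropped(self, tiny_cohort, tmp_path):
        paths = write_cohort(tiny_cohort, tmp_path)
        df = pd.read_csv(paths["visits"])
        df.loc[0, "value"] = np.nan
        df.to_csv(paths["visits"], index=False)
        back = read_cohort(paths["visits"], paths["individuals"], paths["specs"])
        assert len(back.measurements) == 2


class TestNormalization:
    def test_minmax_and_inversion_examples(self):
        m = pd.DataFrame(
            {
                "individual_id": ["p1"] * 3,
                "outcome": ["updrs3", "moca", "moca"],
                "time_years": [0.0, 0.0, 1.0],
                "value": [33.0, 30.0, 24.0],
            }
        )
        specs = {
            "updrs3": OutcomeSpec("updrs3", "continuous", 0, 132),
            "moca": OutcomeSpec("moca", "continuous", 0, 30, invert=True),
        }
        norm = normalize_outcomes(_cohort(m, specs))
        vals = norm.measurements.set_index(["outcome", "time_years"])["value"]
        assert vals.loc[("updrs3", 0.0)] == pytest.approx(0.25)
        assert vals.loc[("moca", 0.0)] == pytest.approx(0.0)  # best score -> 0
        assert vals.loc[("moca", 1.0)] == pytest.approx(0.2)

    def test_endpoints_map_to_unit_interval(self):
        m = pd.DataFrame(
            {
                "individual_id": ["p1"] * 4,
                "outcome": ["a", "a", "b", "b"],
                "time_years": [0.0, 1.0, 0.0, 1.0],
                "value": [10.0, 50.0, 10.0, 50.0],
            }
        )
        specs = {
            "a": OutcomeSpec("a", "continuous", 10, 50),
            "b": OutcomeSpec("b", "continuous", 10, 50, invert=True),
        }
        v = normalize_outcomes(_cohort(m, specs)).measurements.set_index(
            ["outcome", "time_years"]
        )["value"]
        assert (v.loc[("a", 0.0)], v.loc[("a", 1.0)]) == (0.0, 1.0)
        assert (v.loc[("b", 0.0)], v.loc[("b", 1.0)]) == (1.0, 0.0)

    def test_double_normalization_blocked(self, tiny_cohort):
        once = normalize_outcomes(tiny_cohort)
        with pytest.raises(StateError):
            normalize_outcomes(once)

    def test_out_of_range_names_outcome_and_individual(self, tiny_cohort):
        m = tiny_cohort.measurements.copy()
        m.loc[0, "value"] = 200.0
        bad = Cohort("x", tiny_cohort.individuals, m, tiny_cohort.specs)
        with pytest.raises(RangeError, match="updrs3"):
            normalize_outcomes(bad)


class TestInclusionFilters:
    @staticmethod
    def _make(n_ind=35, visits=3, outcome="updrs3"):
        rows = []
        for i in range(n_ind):
            for v in range(visits):
                rows.append((f"p{i}", outcome, float(v), 10.0 + v))
        return pd.DataFrame(
            rows, columns=["individual_id", "outcome", "time_years", "value"]
        )

    def test_single_visit_individual_excluded(self):
        m = self._make(35, 3)
        solo = pd.DataFrame(
            [["solo", "updrs3", 0.0, 10.0]], columns=m.columns
        )
        cohort = _cohort(pd.concat([m, solo], ignore_index=True),
                         {"updrs3": OutcomeSpec("updrs3", "continuous", 0, 132)})
        out = apply_inclusion_filters(cohort)
        assert "solo" not in out.measurements["individual_id"].values
        assert out.filter_report["individuals_removed_min_visits"] == 1

    def test_outcome_below_30_individuals_dropped(self):
        m = self._make(35, 3, "updrs3")
        rare = self._make(29, 3, "rare")
        cohort = _cohort(
            pd.concat([m, rare], ignore_index=True),
            {
                "updrs3": OutcomeSpec("updrs3", "continuous", 0, 132),
                "rare": OutcomeSpec("rare", "continuous", 0, 10),
            },
        )
        out = apply_inclusion_filters(cohort)
        assert "rare" not in set(out.measurements["outcome"])
        assert out.filter_report["outcomes_removed"] == ["rare"]

    def test_boundary_retained(self):
        # exactly 2 visits and exactly 30 individuals: kept
        m = self._make(30, 2)
        out = apply_inclusion_filters(
            _cohort(m, {"updrs3": OutcomeSpec("updrs3", "continuous", 0, 132)})
        )
        assert out.measurements["individual_id"].nunique() == 30

    def test_empty_result_raises(self):
        m = self._make(5, 3)
        with pytest.raises(DegenerateDataError):
            apply_inclusion_filters(
                _cohort(m, {"updrs3": OutcomeSpec("updrs3", "continuous", 0, 132)})
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        min_visits=st.integers(1, 4),
        min_ind=st.integers(1, 40),
        min_meas=st.integers(1, 4),
    )
    def test_filters_monotone_in_thresholds(self, min_visits, min_ind, min_meas):
        """Raising any threshold never increases retained measurements."""
        rng = np.random.default_rng(0)
        rows = []
        for i in range(40):
            nv = rng.integers(1, 5)
            for v in range(nv):
                for k in ("a", "b"):
                    if rng.random() < 0.7:
                        rows.append((f"p{i}", k, float(v), float(rng.integers(0, 10))))
        m = pd.DataFrame(
            rows, columns=["individual_id", "outcome", "time_years", "value"]
        ).drop_duplicates(subset=["individual_id", "outcome", "time_years"])
        specs = {
            "a": OutcomeSpec("a", "continuous", 0, 10),
            "b": OutcomeSpec("b", "continuous", 0, 10),
        }
        cohort = _cohort(m, specs, ids=[f"p{i}" for i in range(40)])

        def count(mv, mi, mm):
            try:
                return len(
                    apply_inclusion_filters(cohort, mv, mi, mm).measurements
                )
            except DegenerateDataError:
                return 0

        base = count(min_visits, min_ind, min_meas)
        assert count(min_visits + 1, min_ind, min_meas) <= base
        assert count(min_visits, min_ind + 5, min_meas) <= base
        assert count(min_visits, min_ind, min_meas + 1) <= base


class TestMotorPhenotype:
    @staticmethod
    def _cohort_with_items(tremor, pigd):
        rows = []
        for i, (tv, pv) in enumerate(zip(tremor, pigd)):
            rows.append((f"p{i}", "tremor_score", 0.0, tv))
            rows.append((f"p{i}", "pigd_score", 0.0, pv))
        m = pd.DataFrame(
            rows, columns=["individual_id", "outcome", "time_years", "value"]
        )
        specs = {
            "tremor_score": OutcomeSpec("tremor_score", "continuous", 0, 4),
            "pigd_score": OutcomeSpec("pigd_score", "continuous", 0, 4),
        }
        return _cohort(m, specs)

    @pytest.mark.parametrize(
        "tremor, pigd, expected",
        [
            (0.8, 0.4, "TD"),  # ratio 2.0
            (0.3, 0.6, "PIGD"),  # ratio 0.5
            (0.5, 0.5, "indeterminate"),  # ratio 1.0, between thresholds
            (0.5, 0.0, "TD"),  # zero PIGD mean, positive tremor
            (0.0, 0.0, "indeterminate"),  # both zero
        ],
    )
    def test_ratio_rules(self, tremor, pigd, expected):
        cohort = self._cohort_with_items([tremor], [pigd])
        labels = classify_motor_phenotype(cohort, ["tremor_score"], ["pigd_score"])
        assert labels.loc["p0"] == expected

    def test_earliest_complete_visit_used(self):
        rows = [
            ("p0", "tremor_score", 0.0, 2.0),  # no pigd at t=0 -> incomplete
            ("p0", "tremor_score", 1.0, 0.3),
            ("p0", "pigd_score", 1.0, 0.6),
        ]
        m = pd.DataFrame(
            rows, columns=["individual_id", "outcome", "time_years", "value"]
        )
        specs = {
            "tremor_score": OutcomeSpec("tremor_score", "continuous", 0, 4),
            "pigd_score": OutcomeSpec("pigd_score", "continuous", 0, 4),
        }
        labels = classify_motor_phenotype(
            _cohort(m, specs), ["tremor_score"], ["pigd_score"]
        )
        assert labels.loc["p0"] == "PIGD"  # from the t=1 visit

    def test_missing_baseline_is_nan(self):
        cohort = self._cohort_with_items([0.8], [0.4])
        # add an individual with no item data at all
        cohort.individuals.loc["p9"] = [60.0, "male"]
        labels = classify_motor_phenotype(cohort, ["tremor_score"], ["pigd_score"])
        assert pd.isna(labels.loc["p9"])
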