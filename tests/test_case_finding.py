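"""Case-finding algorithms: flagging logic, exclusions, cohort assembly."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscomorb.case_finding import (
    CaseAlgorithm,
    apply_algorithm,
    build_cohort,
    count_hospitalizations,
    default_algorithms,
    evaluate_algorithm,
    load_algorithms,
    save_algorithms,
)

WINDOW = (date(2013, 1, 1), date(2017, 12, 31))


def make_events(rows):
    return pd.DataFrame(rows, columns=["subject_id", "stream", "date", "code"])


def simple_algo(**kw):
    base = dict(
        disease="hashimoto_thyroiditis",
        stream_codes={
            "copay_exemption": frozenset({"EXEM:ht"}),
            "hospital_discharge": frozenset({"HOSP:ht"}),
        },
        window=WINDOW,
    )
    base.update(kw)
    return CaseAlgorithm(**base)


def test_single_qualifying_event_flags_subject():
    events = make_events([("p1", "copay_exemption", "2015-06-01", "EXEM:ht")])
    assert apply_algorithm(events, simple_algo()) == {"p1"}


def test_empty_event_table_flags_nobody():
    assert apply_algorithm(make_events([]), simple_algo()) == set()


def test_events_outside_window_or_stream_ignored():
    events = make_events(
        [
            ("p1", "copay_exemption", "2011-06-01", "EXEM:ht"),   # before window
            ("p2", "drug_prescription", "2015-06-01", "EXEM:ht"),  # unlisted stream
            ("p3", "copay_exemption", "2015-06-01", "OTHER"),      # wrong code
        ]
    )
    assert apply_algorithm(events, simple_algo()) == set()


def test_min_count_and_all_rule():
    algo = simple_algo(min_counts={"copay_exemption": 2}, rule="all")
    events = make_events(
        [
            ("p1", "copay_exemption", "2015-06-01", "EXEM:ht"),
            ("p1", "copay_exemption", "2016-06-01", "EXEM:ht"),
            ("p1", "hospital_discharge", "2015-07-01", "HOSP:ht"),
            ("p2", "copay_exemption", "2015-06-01", "EXEM:ht"),  # count 1 < 2
            ("p2", "hospital_discharge", "2015-07-01", "HOSP:ht"),
        ]
    )
    assert apply_algorithm(events, algo) == {"p1"}


def test_thyrotoxic_drug_exclusion_before_first_qualifying_event():
    """A drug-induced case (exclusion code within 12 months before the first
    qualifying event) is vetoed; the same code outside the window is not."""
    algo = simple_algo(exclusion_codes=frozenset({"DRUG:thyrotoxic"}), exclusion_months=12)
    vetoed = make_events(
        [
            ("p1", "copay_exemption", "2015-06-01", "EXEM:ht"),
            ("p1", "drug_prescription", "2014-09-01", "DRUG:thyrotoxic"),
        ]
    )
    assert apply_algorithm(vetoed, algo) == set()
    clear = make_events(
        [
            ("p1", "copay_exemption", "2015-06-01", "EXEM:ht"),
            ("p1", "drug_prescription", "2013-09-01", "DRUG:thyrotoxic"),  # >12 months
            ("p2", "copay_exemption", "2015-06-01", "EXEM:ht"),
            ("p2", "drug_prescription", "2015-09-01", "DRUG:thyrotoxic"),  # after anchor
        ]
    )
    assert apply_algorithm(clear, algo) == {"p1", "p2"}


def test_malformed_date_raises():
    events = make_events([("p1", "copay_exemption", "not-a-date", "EXEM:ht")])
    with pytest.raises((ValueError, pd.errors.ParserError)):
        apply_algorithm(events, simple_algo())


def test_row_permutation_invariance():
    rng = np.random.default_rng(0)
    events = make_events(
        [
            ("p1", "copay_exemption", "2015-06-01", "EXEM:ht"),
            ("p1", "drug_prescription", "2014-09-01", "DRUG:thyrotoxic"),
            ("p2", "hospital_discharge", "2016-01-01", "HOSP:ht"),
            ("p3", "copay_exemption", "2011-01-01", "EXEM:ht"),
        ]
    )
    algo = simple_algo(exclusion_codes=frozenset({"DRUG:thyrotoxic"}))
    ref = apply_algorithm(events, algo)
    for _ in range(5):
        shuffled = events.sample(frac=1.0, random_state=rng.integers(1 << 30)).reset_index(drop=True)
        assert apply_algorithm(shuffled, algo) == ref


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    base_days=st.lists(st.integers(0, 1500), min_size=0, max_size=6),
    extra_days=st.lists(st.integers(0, 1500), min_size=1, max_size=4),
    min_count=st.integers(1, 3),
)
def test_adding_qualifying_events_is_monotone(base_days, extra_days, min_count):
    """Without exclusion rules, more qualifying events never unflag a subject."""
    algo = simple_algo(min_counts={"copay_exemption": min_count})
    start = pd.Timestamp(WINDOW[0])

    def ev(days):
        return make_events(
            [("p1", "copay_exemption", (start + pd.Timedelta(days=d)).date(), "EXEM:ht") for d in days]
        )

    before = apply_algorithm(ev(base_days), algo) if base_days else set()
    after = apply_algorithm(ev(base_days + extra_days), algo)
    assert before.issubset(after)


def test_count_hospitalizations_window_and_stream():
    events = make_events(
        [
            ("p1", "hospital_discharge", "2015-01-01", "ALLCAUSE"),
            ("p1", "hospital_discharge", "2016-01-01", "HOSP:ht"),
            ("p1", "hospital_discharge", "2017-01-01", "ALLCAUSE"),
            ("p1", "hospital_discharge", "2011-01-01", "ALLCAUSE"),  # outside
            ("p1", "hospital_discharge", "2018-06-01", "ALLCAUSE"),  # outside
            ("p2", "drug_prescription", "2015-01-01", "DRUG:x"),
        ]
    )
    assert count_hospitalizations(events, "p1", WINDOW) == 3
    assert count_hospitalizations(events, "p2", WINDOW) == 0  # pharmacy only
    assert count_hospitalizations(events, "nobody", WINDOW) == 0


def test_evaluate_algorithm_exact_corners():
    truth = pd.Series([True, True, False, False], index=["a", "b", "c", "d"])
    perfect = evaluate_algorithm({"a", "b"}, truth)
    assert (perfect.sensitivity, perfect.specificity, perfect.ppv, perfect.npv) == (1, 1, 1, 1)
    inverted = evaluate_algorithm({"c", "d"}, truth)
    assert inverted.sensitivity == 0 and inverted.specificity == 0


def test_build_cohort_age_range_restriction_and_flags():
    subjects = pd.DataFrame(
        {
            "subject_id": ["m1", "m2", "x1", "x2", "x3"],
            "sex": ["female"] * 5,
            "age_years": [18, 80, 50, 85, 10],
            "alive_at_reference": [True, True, True, True, True],
        }
    )
    algos = default_algorithms(diseases=("d1",))
    events = make_events(
        [
            ("m1", "copay_exemption", "2015-01-01", "EXEM:ms"),
            ("m2", "copay_exemption", "2015-01-01", "EXEM:ms"),
            ("x1", "copay_exemption", "2015-01-01", "EXEM:d1"),
        ]
    )
    cohort = build_cohort(subjects, events, algos, date(2017, 12, 31))
    # MS ages span [18, 80]: the 85- and 10-year-old MS-free subjects drop out
    assert set(cohort["subject_id"]) == {"m1", "m2", "x1"}
    row = cohort.set_index("subject_id")
    assert row.loc["m1", "ms_flag"] and not row.loc["x1", "ms_flag"]
    assert row.loc["x1", "aid_d1"] and not row.loc["m1", "aid_d1"]


def test_build_cohort_no_flags_keeps_everyone():
    subjects = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(6)],
            "sex": ["male"] * 6,
            "age_years": [20, 30, 40, 50, 60, 70],
            "alive_at_reference": [True] * 6,
        }
    )
    cohort = build_cohort(subjects, make_events([]), default_algorithms(diseases=("d1",)), date(2017, 12, 31))
    assert len(cohort) == 6
    assert not cohort["ms_flag"].any() and not cohort["aid_d1"].any()
    assert (cohort["hosp_count_5y"] == 0).all()


def test_build_cohort_duplicate_subject_rejected():
    subjects = pd.DataFrame(
        {
            "subject_id": ["a", "a"],
            "sex": ["female", "male"],
            "age_years": [30, 40],
            "alive_at_reference": [True, True],
        }
    )
    with pytest.raises(ValueError, match="duplicate"):
        build_cohort(subjects, make_events([]), default_algorithms(diseases=()), date(2017, 12, 31))


def test_algorithm_yaml_round_trip(tmp_path):
    algos = default_algorithms(diseases=("hashimoto_thyroiditis", "sle"))
    path = tmp_path / "algos.yaml"
    save_algorithms(algos, path)
    loaded = load_algorithms(path)
    assert set(loaded) == set(algos)
    for name in algos:
        a, b = algos[name], loaded[name]
        assert a.stream_codes == b.stream_codes
        assert a.rule == b.rule
        assert a.exclusion_codes == b.exclusion_codes
        assert pd.Timestamp(a.window[0]) == pd.Timestamp(b.window[0])


def test_unknown_stream_rejected():
    with pytest.raises(ValueError, match="stream"):
        CaseAlgorithm(
            disease="x",
            stream_codes={"outpatient_visits": frozenset({"c"})},
            window=WINDOW,
        )
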